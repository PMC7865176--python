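"""File I/O: MRC2014 volumes, tilt-series stacks with .tlt sidecars, and
particle/truth tables (TSV plus a STAR-dialect export).

Volumes are written as MRC2014 mode-2 (float32) maps with the pixel size
encoded in the cell dimensions (cell edge = n_voxels x pixel size), the
convention used across tomography packages. Arrays are (z, y, x) in memory
and x-fastest on disk.
"""

from __future__ import annotations

import os
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

from .volume import TiltSeries, Volume

__all__ = [
    "read_volume",
    "write_volume",
    "read_tilt_series",
    "write_tilt_series",
    "read_table",
    "write_table",
    "write_star",
    "load_yaml",
    "dump_yaml",
]


def _grid_to_mrc(grid_zyx: np.ndarray, pixel_size: float, path: str | os.PathLike) -> None:
    m = gemmi.Ccp4Map()
    # gemmi grids are (nu, nv, nw) = (x, y, z); transpose our (z, y, x)
    m.grid = gemmi.FloatGrid(
        np.ascontiguousarray(grid_zyx.astype(np.float32, copy=False).T)
    )
    nz, ny, nx = grid_zyx.shape
    m.grid.unit_cell = gemmi.UnitCell(
        nx * pixel_size, ny * pixel_size, nz * pixel_size, 90.0, 90.0, 90.0
    )
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def _mrc_to_grid(path: str | os.PathLike) -> tuple[np.ndarray, float]:
    try:
        m = gemmi.read_ccp4_map(str(path))
    except (RuntimeError, ValueError) as exc:  # truncated / malformed header
        raise IOError(f"cannot read MRC map {path!r}: {exc}") from exc
    arr = np.array(m.grid, copy=True)  # (x, y, z)
    if arr.ndim != 3:
        raise IOError(f"{path!r}: expected a 3D map, got shape {arr.shape}")
    px = m.grid.unit_cell.a / m.grid.nu
    if not px > 0:
        raise IOError(f"{path!r}: non-positive pixel size in header (cell.a field)")
    return np.ascontiguousarray(arr.T), float(px)


def write_volume(volume: Volume, path: str | os.PathLike) -> None:
    """Write a Volume as an MRC2014 mode-2 map."""
    _grid_to_mrc(volume.grid, volume.pixel_size, path)


def read_volume(path: str | os.PathLike) -> Volume:
    """Read an MRC/CCP4 map as a Volume; lossless for mode-2 maps."""
    grid, px = _mrc_to_grid(path)
    return Volume(grid, px)


def write_tilt_series(tilt: TiltSeries, path: str | os.PathLike) -> None:
    """Write projections as a multi-frame MRC stack plus an adjacent plain-text
    ``.tlt`` file (one tilt angle per line), the common tomography dialect."""
    _grid_to_mrc(tilt.projections, tilt.pixel_size, path)
    tlt = Path(path).with_suffix(".tlt")
    tlt.write_text("".join(f"{a:.2f}\n" for a in tilt.tilt_angles))


def read_tilt_series(path: str | os.PathLike) -> TiltSeries:
    grid, px = _mrc_to_grid(path)
    tlt = Path(path).with_suffix(".tlt")
    if not tlt.exists():
        raise IOError(f"missing tilt-angle sidecar {tlt}")
    angles = np.array([float(line) for line in tlt.read_text().split()])
    return TiltSeries(grid, angles, px)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_star(df: pd.DataFrame, path: str | os.PathLike, block: str = "particles") -> None:
    """Export a table in a STAR-like dialect (loop_ block, one row per
    particle) for interoperability with EM tool chains."""
    lines = [f"data_{block}", "", "loop_"]
    for i, col in enumerate(df.columns, start=1):
        lines.append(f"_{col} #{i}")
    for _, row in df.iterrows():
        lines.append(" ".join(str(v) for v in row.values))
    Path(path).write_text("\n".join(lines) + "\n")


def load_yaml(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
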