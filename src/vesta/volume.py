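"""Core containers: 3D volumes and single-axis tilt series.

Conventions fixed once for the whole package:

* volumes are indexed ``(z, y, x)``; ``z`` is the electron-beam axis;
* the single tilt axis is ``y``; tilting rotates the specimen in the
  ``(z, x)`` plane;
* all voxel coordinates are 0-based; the rotation / geometric center of an
  ``n``-voxel axis is voxel ``n // 2`` (the FFT origin after ``fftshift``);
* ``pixel_size`` is stored in Å per voxel; physical position = index × pixel
  size. Census and metrics report lengths in nm (1 nm = 10 Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Volume", "TiltSeries"]


@dataclass
class Volume:
    """A 3D scalar grid with a physical pixel size.

    Parameters
    ----------
    grid:
        3D float array, indexed (z, y, x). Stored as float32.
    pixel_size:
        Edge length of one voxel in Å.
    origin:
        Voxel index of the physical origin (informational; defaults to 0).
    """

    grid: np.ndarray
    pixel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3:
            raise ValueError(f"Volume grid must be 3D, got shape {self.grid.shape}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("Volume grid contains non-finite values")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    @property
    def nm_per_voxel(self) -> float:
        return self.pixel_size / 10.0

    def is_cubic(self) -> bool:
        nz, ny, nx = self.grid.shape
        return nz == ny == nx

    def copy(self) -> "Volume":
        return Volume(self.grid.copy(), self.pixel_size, self.origin.copy())


@dataclass
class TiltSeries:
    """Ordered stack of projections from a single-axis tilt experiment.

    ``projections[i]`` is the 2D image (indexed (y, x)) recorded at stage
    tilt ``tilt_angles[i]`` (degrees, strictly increasing).
    """

    projections: np.ndarray
    tilt_angles: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.projections = np.asarray(self.projections, dtype=np.float32)
        self.tilt_angles = np.asarray(self.tilt_angles, dtype=float)
        if self.projections.ndim != 3:
            raise ValueError("projections must be a stack of 2D images")
        if len(self.projections) != len(self.tilt_angles):
            raise ValueError(
                f"{len(self.projections)} projections but "
                f"{len(self.tilt_angles)} tilt angles"
            )
        if len(self.tilt_angles) > 1 and not np.all(np.diff(self.tilt_angles) > 0):
            raise ValueError("tilt angles must be strictly increasing")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    def __len__(self) -> int:
        return len(self.tilt_angles)

    def copy(self) -> "TiltSeries":
        return TiltSeries(
            self.projections.copy(), self.tilt_angles.copy(), self.pixel_size
        )
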