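"""Tomographic core: forward projection, binning, low-pass filtering, and
reconstruction by weighted back-projection (WBP) or SIRT.

The forward model is the ideal single-axis geometry: the specimen is rotated
about ``y`` by the stage tilt and integrated along the beam axis ``z``. The
back-projector is the adjoint built from the same bilinear rotator. SIRT uses
the standard component-wise row/column normalization

    x  <-  x + relax * C^-1 A^T R^-1 (b - A x)

with R = row sums (projection of a ones volume) and C = column sums
(back-projection of ones projections); the data residual ||b - Ax|| must be
non-increasing on consistent data and reconstruction aborts if it grows.
"""

from __future__ import annotations

import numpy as np

from .transform import rotate_about_y
from .volume import TiltSeries, Volume

__all__ = [
    "tilt_angles",
    "project",
    "bin_volume",
    "lowpass",
    "reconstruct_wbp",
    "reconstruct_sirt",
]


def tilt_angles(tilt_min: float, tilt_max: float, tilt_step: float) -> np.ndarray:
    """Tilt scheme: floor((max - min)/step) + 1 angles starting at tilt_min."""
    if not (tilt_min < 0 < tilt_max):
        raise ValueError("tilt range must straddle 0")
    if not tilt_step > 0:
        raise ValueError("tilt_step must be positive")
    n = int(np.floor((tilt_max - tilt_min) / tilt_step)) + 1
    return tilt_min + tilt_step * np.arange(n)


def _forward_one(grid: np.ndarray, angle: float) -> np.ndarray:
    return rotate_about_y(grid, angle).sum(axis=0)


def _back_one(proj: np.ndarray, angle: float, nz: int) -> np.ndarray:
    smear = np.broadcast_to(proj[None, :, :], (nz,) + proj.shape)
    return rotate_about_y(np.ascontiguousarray(smear), -angle)


def project(volume: Volume, angles: np.ndarray) -> TiltSeries:
    """Line-integral projections of a cubic volume at the given stage tilts."""
    if not volume.is_cubic():
        raise ValueError(f"projection requires a cubic volume, got {volume.shape}")
    angles = np.asarray(angles, dtype=float)
    projs = np.stack([_forward_one(volume.grid, a) for a in angles])
    return TiltSeries(projs, angles, volume.pixel_size)


def bin_volume(v: Volume, factor: int, policy: str = "strict") -> Volume:
    """Mean-pool by ``factor`` in each dimension; pixel size scales by factor.

    ``policy='strict'`` requires divisible dimensions; ``policy='crop'``
    truncates each axis to the largest multiple first.
    """
    if factor < 1 or int(factor) != factor:
        raise ValueError("bin factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return v.copy()
    g = v.grid
    if any(s % factor for s in g.shape):
        if policy != "crop":
            raise ValueError(
                f"dimensions {g.shape} not divisible by {factor}; pass policy='crop'"
            )
        g = g[tuple(slice(0, (s // factor) * factor) for s in g.shape)]
    nz, ny, nx = (s // factor for s in g.shape)
    g = g.reshape(nz, factor, ny, factor, nx, factor).mean(axis=(1, 3, 5))
    return Volume(g, v.pixel_size * factor)


def lowpass(v: Volume, cutoff: float, softness: float = 0.1) -> Volume:
    """Low-pass filter with a cosine-edge window.

    ``cutoff`` is in 1/nm; the window is 1 up to cutoff*(1 - softness),
    rolls off as a raised cosine, and is 0 beyond cutoff*(1 + softness).
    softness=0 gives a hard cutoff (identity when cutoff = Nyquist).
    """
    d_nm = v.nm_per_voxel
    nyquist = 1.0 / (2.0 * d_nm)
    if not 0 < cutoff <= nyquist + 1e-9:
        raise ValueError(f"cutoff {cutoff} 1/nm outside (0, Nyquist={nyquist:.4f}]")
    nz, ny, nx = v.shape
    kz = np.fft.fftfreq(nz, d=d_nm)[:, None, None]
    ky = np.fft.fftfreq(ny, d=d_nm)[None, :, None]
    kx = np.fft.rfftfreq(nx, d=d_nm)[None, None, :]
    k = np.sqrt(kz**2 + ky**2 + kx**2)
    w = softness * cutoff
    lo, hi = cutoff - w, cutoff + w
    win = np.ones_like(k)
    if w > 0:
        edge = (k > lo) & (k < hi)
        win[edge] = 0.5 * (1.0 + np.cos(np.pi * (k[edge] - lo) / (2.0 * w)))
    win[k > hi] = 0.0
    if softness == 0 and cutoff >= nyquist * (1 - 1e-9):
        # the pass band covers every representable axis frequency: identity
        win[:] = 1.0
    out = np.fft.irfftn(np.fft.rfftn(v.grid) * win, s=v.shape,
                        axes=(0, 1, 2))
    return Volume(out, v.pixel_size)


def _ramp_filter(projs: np.ndarray) -> np.ndarray:
    """Ramp-filter each projection along the detector axis x."""
    nx = projs.shape[-1]
    ramp = np.abs(np.fft.rfftfreq(nx))
    f = np.fft.rfft(projs, axis=-1)
    return np.fft.irfft(f * ramp[None, None, :], n=nx, axis=-1).astype(np.float32)


def reconstruct_wbp(tilt: TiltSeries, size: int | None = None) -> Volume:
    """Weighted (ramp-filtered) back-projection onto a cubic grid."""
    ny, nx = tilt.projections.shape[1:]
    nz = size if size is not None else nx
    filtered = _ramp_filter(tilt.projections)
    out = np.zeros((nz, ny, nx), dtype=np.float32)
    for p, a in zip(filtered, tilt.tilt_angles):
        out += _back_one(p, a, nz)
    out *= np.pi / (2.0 * max(len(tilt), 1))
    return Volume(out, tilt.pixel_size)


def reconstruct_sirt(
    tilt: TiltSeries,
    n_iter: int = 30,
    relax: float = 1.0,
    size: int | None = None,
    divergence_factor: float = 1.1,
) -> Volume:
    """SIRT reconstruction with ray-length normalization.

    Raises RuntimeError if the data residual grows by more than
    ``divergence_factor`` between iterations (advice: reduce ``relax``).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    b = tilt.projections.astype(np.float32)
    angles = tilt.tilt_angles
    if len(angles) == 0:
        raise ValueError("empty tilt series")
    ny, nx = b.shape[1:]
    nz = size if size is not None else nx
    ones_vol = np.ones((nz, ny, nx), dtype=np.float32)
    row = np.stack([_forward_one(ones_vol, a) for a in angles])  # R
    ones_proj = np.ones_like(b)
    col = np.zeros((nz, ny, nx), dtype=np.float32)  # C
    for p, a in zip(ones_proj, angles):
        col += _back_one(p, a, nz)
    row = np.maximum(row, 1e-6)
    col = np.maximum(col, 1e-6)
    # voxels outside the inscribed cylinder in the tilt plane rotate out of
    # the field of view and are never consistently sampled; keep them at 0
    zi = (np.arange(nz) - nz // 2)[:, None]
    xi = (np.arange(nx) - nx // 2)[None, :]
    support = (zi**2 + xi**2 <= (min(nz, nx) / 2.0) ** 2)
    support = support[:, None, :].astype(np.float32)

    x = np.zeros((nz, ny, nx), dtype=np.float32)
    prev_res = None
    for _ in range(n_iter):
        fx = np.stack([_forward_one(x, a) for a in angles])
        resid = b - fx
        res_norm = float(np.linalg.norm(resid))
        if prev_res is not None and res_norm > divergence_factor * prev_res:
            raise RuntimeError(
                f"SIRT diverging (residual {res_norm:.3g} > "
                f"{divergence_factor} x {prev_res:.3g}); reduce relax"
            )
        prev_res = res_norm
        upd = np.zeros_like(x)
        for p, a in zip(resid / row, angles):
            upd += _back_one(p, a, nz)
        x += relax * upd / col * support
    return Volume(x, tilt.pixel_size)
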