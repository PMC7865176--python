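"""Rotation, shift and resampling primitives.

Real-space rotations use linear interpolation throughout. Single-plane
rotations (about the tilt axis ``y`` or the docking axis ``z``) are the hot
path of projection, back-projection and in-plane ("spin") alignment, so they
are implemented as cached bilinear gathers vectorized over the untouched
axis; general rotations fall back to ``scipy.ndimage.affine_transform``.

Euler angles follow the ZYZ convention, intrinsic, in degrees:
``R = Rz(alpha) @ Ry(beta) @ Rz(gamma)`` acting on physical (x, y, z)
column vectors. Shifts are in voxels and are applied after rotation.
The rotation center of an ``n``-voxel axis is voxel ``n // 2``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = [
    "euler_zyz_matrix",
    "axis_to_z_euler",
    "rotate_plane",
    "rotate_volume",
    "rotation_about_z_angle",
    "fourier_shift",
]

# physical (x,y,z) index -> array (z,y,x) index permutation
_PERM = np.array([2, 1, 0])


def euler_zyz_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """3x3 rotation matrix for intrinsic ZYZ Euler angles in degrees.

    Acts on physical (x, y, z) column vectors.
    """
    a, b, g = np.deg2rad([alpha, beta, gamma])

    def rz(t):
        c, s = np.cos(t), np.sin(t)
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])

    def ry(t):
        c, s = np.cos(t), np.sin(t)
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])

    return rz(a) @ ry(b) @ rz(g)


def axis_to_z_euler(axis: np.ndarray) -> tuple[float, float, float]:
    """Euler angles (alpha=0, beta, gamma) whose rotation maps ``axis`` to +z.

    ``axis`` is a 3-vector in physical (x, y, z) order; need not be unit.
    """
    v = np.asarray(axis, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("cannot orient a zero-length axis")
    v = v / n
    theta = np.rad2deg(np.arccos(np.clip(v[2], -1.0, 1.0)))
    phi = np.rad2deg(np.arctan2(v[1], v[0]))
    # Rz(gamma=-phi) brings axis into the xz-plane, Ry(beta=-theta) lifts to +z
    return (0.0, -theta, -phi)


def rotation_about_z_angle(rot: np.ndarray, tol: float = 1e-10) -> float | None:
    """If ``rot`` (physical xyz) is a pure rotation about z, return its angle
    in degrees, else None."""
    if abs(rot[2, 2] - 1.0) < tol and abs(rot[0, 2]) < tol and abs(rot[1, 2]) < tol \
            and abs(rot[2, 0]) < tol and abs(rot[2, 1]) < tol:
        return float(np.rad2deg(np.arctan2(rot[1, 0], rot[0, 0])))
    return None


# ---------------------------------------------------------------------------
# cached bilinear in-plane rotators
# ---------------------------------------------------------------------------

_PLANE_CACHE: dict[tuple, tuple] = {}
_PLANE_CACHE_MAX = 512


def _plane_maps(n0: int, n1: int, angle_deg: float):
    """Bilinear gather maps for rotating content by +angle in a (a0, a1)
    plane, where a0 is 'z-like' and a1 is 'x-like' (right-handed: +angle
    moves a feature on +a1 toward +a0)."""
    key = (n0, n1, round(float(angle_deg), 6))
    hit = _PLANE_CACHE.get(key)
    if hit is not None:
        return hit
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    c0, c1 = n0 // 2, n1 // 2
    i0, i1 = np.meshgrid(
        np.arange(n0) - c0, np.arange(n1) - c1, indexing="ij"
    )
    # inverse mapping (rotate sample coords by -angle)
    src0 = c * i0 - s * i1 + c0
    src1 = s * i0 + c * i1 + c1
    f0 = np.floor(src0).astype(np.int64)
    f1 = np.floor(src1).astype(np.int64)
    r0 = (src0 - f0).astype(np.float32)
    r1 = (src1 - f1).astype(np.float32)
    idx = []
    wts = []
    for d0 in (0, 1):
        for d1 in (0, 1):
            j0 = f0 + d0
            j1 = f1 + d1
            valid = (j0 >= 0) & (j0 < n0) & (j1 >= 0) & (j1 < n1)
            w = (r0 if d0 else 1.0 - r0) * (r1 if d1 else 1.0 - r1)
            w = np.where(valid, w, 0.0).astype(np.float32)
            idx.append((np.clip(j0, 0, n0 - 1), np.clip(j1, 0, n1 - 1)))
            wts.append(w)
    out = (idx, wts)
    if len(_PLANE_CACHE) >= _PLANE_CACHE_MAX:
        _PLANE_CACHE.clear()
    _PLANE_CACHE[key] = out
    return out


def rotate_plane(grid: np.ndarray, angle_deg: float, axes: tuple[int, int]) -> np.ndarray:
    """Rotate a 3D array's content by +angle degrees in the plane spanned by
    ``axes`` = (z-like, x-like), vectorized over the remaining axis.

    ``axes=(0, 2)`` rotates about y (tilt geometry); ``axes=(1, 2)`` rotates
    about z when combined with the (z, y, x) layout: +angle moves +x toward +y,
    i.e. a right-handed rotation about +z for axes=(1, 2).
    """
    if angle_deg == 0.0:
        return grid.astype(np.float32, copy=True)
    a0, a1 = axes
    other = ({0, 1, 2} - {a0, a1}).pop()
    v = np.ascontiguousarray(np.moveaxis(grid, other, 0).astype(np.float32, copy=False))
    n0, n1 = v.shape[1], v.shape[2]
    idx, wts = _plane_maps(n0, n1, angle_deg)
    out = np.zeros_like(v)
    for (j0, j1), w in zip(idx, wts):
        out += w[None, :, :] * v[:, j0, j1]
    return np.moveaxis(out, 0, other)


def rotate_about_y(grid: np.ndarray, angle_deg: float) -> np.ndarray:
    """Tilt-geometry rotation: +angle moves a feature on +x toward +z."""
    return rotate_plane(grid, angle_deg, axes=(0, 2))


def rotate_about_z(grid: np.ndarray, angle_deg: float) -> np.ndarray:
    """In-plane spin: right-handed rotation about +z (+x toward +y)."""
    return rotate_plane(grid, angle_deg, axes=(1, 2))


def rotate_volume(grid: np.ndarray, rot: np.ndarray,
                  order: int = 1) -> np.ndarray:
    """Rotate content of a (z, y, x) array by the physical-frame matrix ``rot``.

    ``order=1``: linear interpolation, with a fast cached path for pure
    z-rotations — the alignment workhorse. ``order=3``: cubic B-spline with
    prefiltering — used when building final averages, where the stronger
    high-frequency attenuation of linear interpolation would drag sharp
    features down local intensity gradients.
    """
    if order == 1:
        zangle = rotation_about_z_angle(rot)
        if zangle is not None:
            return rotate_about_z(grid, zangle)
    # array-axes matrix: A = P R P^T with P the xyz->zyx permutation
    A = rot[np.ix_(_PERM, _PERM)]
    center = np.array([s // 2 for s in grid.shape], dtype=float)
    Minv = A.T  # inverse mapping for affine_transform
    offset = center - Minv @ center
    return ndimage.affine_transform(
        grid.astype(np.float32, copy=False), Minv, offset=offset, order=order,
        prefilter=(order > 1), mode="constant", cval=0.0,
    )


def fourier_shift(grid: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Subvoxel translation by ``shift`` voxels (z, y, x order) via Fourier
    phase ramps. Periodic boundary; callers keep shifts small."""
    shift = np.asarray(shift, dtype=float)
    if np.all(shift == 0):
        return grid.astype(np.float32, copy=True)
    f = np.fft.rfftn(grid)
    nz, ny, nx = grid.shape
    kz = np.fft.fftfreq(nz)[:, None, None]
    ky = np.fft.fftfreq(ny)[None, :, None]
    kx = np.fft.rfftfreq(nx)[None, None, :]
    phase = np.exp(-2j * np.pi * (kz * shift[0] + ky * shift[1] + kx * shift[2]))
    return np.fft.irfftn(f * phase, s=grid.shape, axes=(0, 1, 2)).astype(np.float32)
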