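"""Missing-wedge-aware subtomogram alignment, classification, averaging and
Cn symmetrization.

Everything operates in the docking frame: ``init_pose`` rotates each
particle so its docking axis (vesicle center -> membrane contact point)
lies along +z and the docking midpoint sits at the box center. The missing
wedge of every particle is carried along as an analytic Fourier-domain mask
whose orientation composes with the particle's pose, so constrained
cross-correlations and wedge-compensated averages always know which Fourier
voxels were actually measured.

Conventions: Euler angles ZYZ, intrinsic, degrees; shifts in voxels,
physical (x, y, z) order, applied after rotation about the box center
(voxel n//2 per axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation as _Rot

from .transform import fourier_shift, rotate_about_z, rotate_volume
from .volume import Volume

__all__ = [
    "WedgeMask",
    "Pose",
    "ClassAverage",
    "make_wedge_mask",
    "constrained_cc",
    "init_pose",
    "align_one",
    "msa_classify",
    "wedge_compensated_average",
    "apply_cn_symmetry",
    "refine",
    "RefineConfig",
    "sphere_mask",
    "cylinder_mask",
]


# ---------------------------------------------------------------------------
# wedge masks
# ---------------------------------------------------------------------------

_FREQ_CACHE: dict[tuple, tuple] = {}


def _freq_grids(shape: tuple[int, int, int], half: bool):
    key = (shape, half)
    hit = _FREQ_CACHE.get(key)
    if hit is None:
        nz, ny, nx = shape
        kz = np.fft.fftfreq(nz)[:, None, None]
        ky = np.fft.fftfreq(ny)[None, :, None]
        kxf = np.fft.rfftfreq(nx) if half else np.fft.fftfreq(nx)
        kx = kxf[None, None, :]
        hit = np.broadcast_arrays(kx, ky, kz)
        hit = tuple(a.astype(np.float32) for a in hit)
        _FREQ_CACHE[key] = hit
    return hit


@dataclass
class WedgeMask:
    """Fourier support of a single-axis tilt range (wedge about the y axis).

    A Fourier voxel is measured iff the angle of its (kz, kx) component from
    the kx axis lies within [tilt_min, tilt_max]; ``orientation`` (a rotation
    matrix acting on physical xyz) rotates the mask into the particle frame
    and composes with every pose applied to the particle. ``apodization``
    adds a cosine taper of that angular width (degrees) at the wedge edge.
    """

    tilt_min: float
    tilt_max: float
    shape: tuple[int, int, int]
    orientation: np.ndarray | None = None
    apodization: float = 0.0

    def __post_init__(self) -> None:
        if not (-90 <= self.tilt_min < 0 < self.tilt_max <= 90):
            raise ValueError(
                f"tilt range ({self.tilt_min}, {self.tilt_max}) must lie "
                "inside [-90, 90] and straddle 0"
            )

    def rotated(self, rot: np.ndarray) -> "WedgeMask":
        """Mask of the same data after rotating the particle by ``rot``."""
        base = self.orientation if self.orientation is not None else np.eye(3)
        return WedgeMask(self.tilt_min, self.tilt_max, self.shape,
                         orientation=rot @ base, apodization=self.apodization)

    def array(self, half: bool = False) -> np.ndarray:
        """Evaluate the mask on the (r)fft frequency grid.

        Hermitian by construction (mask(k) = mask(-k)): the Nyquist planes
        of an even grid represent +-0.5 ambiguously, so a voxel there counts
        as measured only if both sign assignments fall inside the tilt range.
        """
        kx, ky, kz = _freq_grids(self.shape, False)
        if self.orientation is not None:
            # spectrum of the rotated particle: mask(R^-1 k)
            Rinv = np.asarray(self.orientation, dtype=np.float32).T
            kx, ky, kz = (
                Rinv[0, 0] * kx + Rinv[0, 1] * ky + Rinv[0, 2] * kz,
                Rinv[1, 0] * kx + Rinv[1, 1] * ky + Rinv[1, 2] * kz,
                Rinv[2, 0] * kx + Rinv[2, 1] * ky + Rinv[2, 2] * kz,
            )
        ang = np.rad2deg(np.arctan2(np.abs(kz), np.abs(kx)))
        lim = min(-self.tilt_min, self.tilt_max)
        if self.apodization <= 0:
            m = (ang <= lim).astype(np.float32)
        else:
            m = np.clip((lim + self.apodization - ang) / self.apodization,
                        0.0, 1.0).astype(np.float32)
        m = np.minimum(m, np.roll(m[::-1, ::-1, ::-1], 1, axis=(0, 1, 2)))
        m.flat[0] = 1.0  # DC is always measured
        if half:
            return np.ascontiguousarray(m[:, :, : self.shape[2] // 2 + 1])
        return m

    def covered_fraction(self) -> float:
        """Measured fraction of the Nyquist ball (≈ tilt span / 180°)."""
        kx, ky, kz = _freq_grids(self.shape, False)
        ball = (kx**2 + ky**2 + kz**2) <= 0.25
        return float(self.array()[ball].mean())


def make_wedge_mask(
    shape: tuple[int, int, int],
    tilt_min: float,
    tilt_max: float,
    orientation: np.ndarray | None = None,
    apodization: float = 0.0,
) -> WedgeMask:
    return WedgeMask(tilt_min, tilt_max, tuple(shape), orientation, apodization)


# ---------------------------------------------------------------------------
# poses
# ---------------------------------------------------------------------------

@dataclass
class Pose:
    """Rigid transform: intrinsic ZYZ rotation (deg) then a voxel shift."""

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shift: np.ndarray = field(default_factory=lambda: np.zeros(3))  # xyz voxels

    def __post_init__(self) -> None:
        self.shift = np.asarray(self.shift, dtype=float)

    @property
    def matrix(self) -> np.ndarray:
        return _Rot.from_euler("ZYZ", self.rotation, degrees=True).as_matrix()

    @classmethod
    def from_matrix(cls, rot: np.ndarray, shift=None) -> "Pose":
        import warnings as _warnings
        with _warnings.catch_warnings():
            # beta = 0 or 180 leaves alpha+gamma determined only jointly;
            # scipy's canonical choice (gamma = 0) is fine for us
            _warnings.simplefilter("ignore", UserWarning)
            eul = _Rot.from_matrix(rot).as_euler("ZYZ", degrees=True)
        return cls(tuple(eul), np.zeros(3) if shift is None else shift)

    def compose(self, outer: "Pose") -> "Pose":
        """Pose equivalent to applying ``self`` then ``outer``."""
        rot = outer.matrix @ self.matrix
        shift = outer.matrix @ self.shift + outer.shift
        return Pose.from_matrix(rot, shift)


def apply_pose(vol: Volume, pose: Pose, order: int = 1) -> Volume:
    """Rotate about the box center, then shift (interpolated rotation /
    Fourier-phase shift)."""
    g = rotate_volume(vol.grid, pose.matrix, order=order)
    if np.any(pose.shift != 0):
        g = fourier_shift(g, pose.shift[::-1])  # to (z, y, x)
    return Volume(g, vol.pixel_size)


def init_pose(
    center_vox: np.ndarray,
    contact_vox: np.ndarray,
    box_size: int,
    mid_radius_vox: float | None = None,
) -> Pose:
    """Initial pose from picked coordinates: the docking axis (vesicle
    center -> membrane contact) maps onto +z, the in-plane spin is zero, and
    the docking midpoint (between vesicle mid-surface and contact point, if
    the radius is known, else the contact point) lands on the box center.

    ``center_vox``/``contact_vox`` are voxel coordinates in (x, y, z) order.
    """
    center_vox = np.asarray(center_vox, float)
    contact_vox = np.asarray(contact_vox, float)
    d = contact_vox - center_vox
    norm = np.linalg.norm(d)
    if norm == 0:
        raise ValueError("zero-length docking vector")
    d_hat = d / norm
    from .transform import axis_to_z_euler
    eul = axis_to_z_euler(d_hat)
    rot = _Rot.from_euler("ZYZ", eul, degrees=True).as_matrix()
    if mid_radius_vox is not None:
        midpoint = center_vox + (mid_radius_vox + (norm - mid_radius_vox) / 2.0) * d_hat
    else:
        midpoint = contact_vox
    c = np.full(3, box_size // 2, dtype=float)
    shift = -(rot @ (midpoint - c))
    return Pose(tuple(eul), shift)


# ---------------------------------------------------------------------------
# constrained cross-correlation
# ---------------------------------------------------------------------------

class UndefinedScoreError(RuntimeError):
    """Constrained CC undefined: empty mask intersection or zero energy."""


def constrained_cc(
    a: Volume | np.ndarray,
    b: Volume | np.ndarray,
    wa: WedgeMask | None = None,
    wb: WedgeMask | None = None,
) -> float:
    """Normalized cross-correlation restricted to the common Fourier support.

    Both spectra are restricted to M = wa ∩ wb, the zero-frequency term is
    removed (equivalent to mean subtraction of the M-filtered volumes), and
    each factor is normalized by its energy within M; the score lies in
    [-1, 1] with 1 for identical volumes.
    """
    ga = a.grid if isinstance(a, Volume) else np.asarray(a)
    gb = b.grid if isinstance(b, Volume) else np.asarray(b)
    if ga.shape != gb.shape:
        raise ValueError(f"shape mismatch {ga.shape} vs {gb.shape}")
    fa = np.fft.fftn(ga)
    fb = np.fft.fftn(gb)
    m = np.ones(ga.shape, dtype=np.float32)
    if wa is not None:
        m = m * wa.array()
    if wb is not None:
        m = m * wb.array()
    m.flat[0] = 0.0  # remove DC: mean subtraction within M
    if not np.any(m > 0):
        raise UndefinedScoreError("empty wedge-mask intersection")
    num = float(np.real(np.vdot(fa * m, fb * m)))
    ea = float(np.real(np.vdot(fa * m, fa * m)))
    eb = float(np.real(np.vdot(fb * m, fb * m)))
    if ea <= 0 or eb <= 0:
        raise UndefinedScoreError("zero energy inside the mask")
    return num / np.sqrt(ea * eb)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _rotation_grid(cone_deg: float, cone_step: float, spin_step: float,
                   spin_range: tuple[float, float] = (0.0, 360.0)):
    """Deterministic list of (psi, azimuth, spin) candidate rotations:
    a cone around +z crossed with in-plane spin."""
    axes = [(0.0, 0.0)]
    if cone_deg > 0 and cone_step > 0:
        for psi in np.arange(cone_step, cone_deg + 1e-9, cone_step):
            n_az = max(int(round(360.0 * np.sin(np.deg2rad(psi)) / cone_step)), 1)
            for az in np.arange(0.0, 360.0, 360.0 / n_az):
                axes.append((float(psi), float(az)))
    spins = np.arange(spin_range[0], spin_range[1] - 1e-9, spin_step)
    return [(psi, az, float(s)) for (psi, az) in axes for s in spins]


def _candidate_matrix(psi: float, az: float, spin: float) -> np.ndarray:
    return _Rot.from_euler("ZYZ", [az, psi, spin - az], degrees=True).as_matrix()


def align_one(
    sub: Volume,
    wedge: WedgeMask,
    ref: Volume,
    cone_deg: float = 0.0,
    cone_step: float = 5.0,
    spin_step: float = 3.0,
    spin_range: tuple[float, float] = (0.0, 360.0),
    shift_radius: float = 0.0,
    focus_mask: np.ndarray | None = None,
) -> tuple[Pose, float]:
    """Exhaustive constrained-CC search over a cone x spin x shift grid.

    The particle is assumed to be in the docking frame already (init pose
    applied); the reference is rotated by each inverse candidate so the
    particle's wedge mask stays fixed. Ties break to the earliest rotation
    in grid order and the lexicographically smallest shift.
    """
    grid = _rotation_grid(cone_deg, cone_step, spin_step, spin_range)
    g_sub = sub.grid if focus_mask is None else sub.grid * focus_mask
    fa = np.fft.fftn(g_sub)
    m = wedge.array()
    m.flat[0] = 0.0
    ea = float(np.real(np.vdot(fa * m, fa * m)))
    if ea <= 0:
        raise UndefinedScoreError("flat subtomogram inside the mask")
    best = (-np.inf, None, np.zeros(3))
    nz = sub.shape[0]
    for (psi, az, spin) in grid:
        rot = _candidate_matrix(psi, az, spin)
        g_ref = rotate_volume(ref.grid, rot.T)
        if focus_mask is not None:
            g_ref = g_ref * focus_mask
        fb = np.fft.fftn(g_ref)
        eb = float(np.real(np.vdot(fb * m, fb * m)))
        if eb <= 0:
            continue
        prod = fa * np.conj(fb) * m
        if shift_radius <= 0:
            score = float(np.real(prod.sum())) / np.sqrt(ea * eb)
            shift = np.zeros(3)
        else:
            ccmap = np.real(np.fft.ifftn(prod)) * prod.size / np.sqrt(ea * eb)
            r = int(np.ceil(shift_radius))
            offs = np.arange(-r, r + 1)
            zz, yy, xx = np.meshgrid(offs, offs, offs, indexing="ij")
            inside = zz**2 + yy**2 + xx**2 <= shift_radius**2
            vals = ccmap[zz % nz, yy % nz, xx % nz]
            vals = np.where(inside, vals, -np.inf)
            i = int(np.argmax(vals))
            score = float(vals.flat[i])
            # content moved by -offset maximizes match after shifting by it
            shift = np.array([xx.flat[i], yy.flat[i], zz.flat[i]], float)
        if score > best[0]:
            best = (score, rot, shift)
    if best[1] is None:
        raise UndefinedScoreError("no defined score on the search grid")
    return Pose.from_matrix(best[1], best[2]), best[0]


def _half_weights(shape: tuple[int, int, int]) -> np.ndarray:
    """Multiplicities of rfftn coefficients for full-spectrum sums."""
    nz, ny, nx = shape
    w = np.full((nz, ny, nx // 2 + 1), 2.0, dtype=np.float32)
    w[:, :, 0] = 1.0
    if nx % 2 == 0:
        w[:, :, -1] = 1.0
    return w


def align_spins(
    subs: list[Volume],
    wedges: list[WedgeMask],
    ref: Volume,
    spin_step: float,
    spin_windows: list[tuple[float, float]] | None = None,
    focus_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Batch in-plane spin alignment of many particles against one reference.

    Equivalent to ``align_one`` with a spin-only grid but sharing the
    rotated-reference FFTs across particles. Returns (best spins deg,
    scores).
    """
    shape = subs[0].shape
    w = _half_weights(shape)
    w.flat[0] = 0.0  # exclude DC everywhere
    spins = np.arange(0.0, 360.0, spin_step)
    n = len(subs)
    F = np.empty((n,) + w.shape, dtype=np.complex64)
    M = np.empty((n,) + w.shape, dtype=np.float32)
    for i, (s, wd) in enumerate(zip(subs, wedges)):
        g = s.grid if focus_mask is None else s.grid * focus_mask
        F[i] = np.fft.rfftn(g)
        M[i] = wd.array(half=True) * w
    ea = np.einsum("nijk,nijk->n", np.abs(F) ** 2, M)
    scores = np.full((n, len(spins)), -np.inf, dtype=np.float64)
    for j, spin in enumerate(spins):
        g_ref = rotate_about_z(ref.grid, -spin)
        if focus_mask is not None:
            g_ref = g_ref * focus_mask
        G = np.fft.rfftn(g_ref).astype(np.complex64)
        num = np.einsum("nijk,nijk->n", np.real(F * np.conj(G)[None]), M)
        eb = np.einsum("nijk,ijk->n", M, np.abs(G) ** 2)
        ok = (ea > 0) & (eb > 0)
        scores[ok, j] = num[ok] / np.sqrt(ea[ok] * eb[ok])
    if spin_windows is not None:
        for i, (lo, hi) in enumerate(spin_windows):
            d = (spins - lo) % 360.0
            width = (hi - lo) % 360.0
            outside = d > width
            scores[i, outside] = -np.inf
    best = np.argmax(scores, axis=1)
    return spins[best], scores[np.arange(n), best]


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def msa_classify(
    subs: list[Volume],
    wedges: list[WedgeMask] | None,
    n_components: int = 8,
    n_classes: int = 10,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Multivariate statistical analysis + hierarchical ascendant
    classification.

    Pipeline: restrict each particle's spectrum to its wedge support, take
    the voxels inside the real-space mask as features, reduce with PCA and
    cut a Ward-linkage agglomerative tree at ``n_classes``. Deterministic
    given the input order; labels are renumbered by first appearance.
    """
    from sklearn.cluster import AgglomerativeClustering
    from sklearn.decomposition import PCA

    n = len(subs)
    if n_classes > n:
        raise ValueError(f"n_classes {n_classes} > n_particles {n}")
    if n_classes == 1:
        return np.zeros(n, dtype=int)
    feats = []
    for i, s in enumerate(subs):
        g = s.grid
        if wedges is not None:
            f = np.fft.rfftn(g) * wedges[i].array(half=True)
            g = np.fft.irfftn(f, s=g.shape, axes=(0, 1, 2))
        feats.append(g[mask > 0.5] if mask is not None else g.ravel())
    X = np.asarray(feats, dtype=np.float64)
    X -= X.mean(axis=0, keepdims=True)
    k = min(n_components, n - 1, X.shape[1])
    scores = PCA(n_components=k, svd_solver="full").fit_transform(X)
    labels = AgglomerativeClustering(
        n_clusters=n_classes, linkage="ward"
    ).fit_predict(scores)
    # canonical numbering by first appearance
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return out


# ---------------------------------------------------------------------------
# averaging and symmetry
# ---------------------------------------------------------------------------

@dataclass
class ClassAverage:
    """Wedge-compensated average with its membership and coverage map."""

    volume: Volume
    members: list[int]
    symmetry: int = 1
    wedge_coverage: np.ndarray | None = None  # rfftn-layout counts
    provenance: dict = field(default_factory=dict)

    def uncovered_fraction(self) -> float:
        if self.wedge_coverage is None:
            return 0.0
        return float((self.wedge_coverage <= 0).mean())


def wedge_compensated_average(
    subs: list[Volume],
    poses: list[Pose],
    wedges: list[WedgeMask],
    members: list[int] | None = None,
    coverage_floor: float = 1.0,
    order: int = 3,
) -> ClassAverage:
    """Average particles in the common frame, dividing the summed spectra by
    the accumulated wedge coverage (floored) so orientations that sample a
    Fourier region more often do not dominate it.

    Cubic interpolation by default: the average is a measurement product,
    and linear interpolation's attenuation drags sharp features down local
    intensity gradients by a few tenths of a nanometre.
    """
    if len(subs) == 0:
        raise ValueError("cannot average an empty particle set")
    shape = subs[0].shape
    S = np.zeros((shape[0], shape[1], shape[2] // 2 + 1), dtype=np.complex128)
    C = np.zeros(S.shape, dtype=np.float64)
    for s, p, wd in zip(subs, poses, wedges):
        t = apply_pose(s, p, order=order)
        S += np.fft.rfftn(t.grid)
        C += wd.rotated(p.matrix).array(half=True)
    avg = np.fft.irfftn(S / np.maximum(C, coverage_floor), s=shape,
                         axes=(0, 1, 2))
    prov = {"n_members": len(subs),
            "uncovered_fraction": float((C <= 0).mean())}
    if prov["uncovered_fraction"] > 0.2:
        prov["warning"] = "more than 20% of Fourier space uncovered"
    vol = Volume(avg, subs[0].pixel_size)
    return ClassAverage(vol, members if members is not None else
                        list(range(len(subs))), 1, C, prov)


def apply_cn_symmetry(v: Volume, n: int, axis: np.ndarray | None = None,
                      order: int = 3) -> Volume:
    """Mean of the volume over the n rotations of the Cn group about
    ``axis`` (default +z, the docking axis). Idempotent; n=1 is identity.

    Cubic interpolation by default (measurement product; see
    ``wedge_compensated_average``).
    """
    if n < 1 or int(n) != n:
        raise ValueError("symmetry order must be a positive integer")
    n = int(n)
    if n == 1:
        return v.copy()
    acc = np.zeros_like(v.grid, dtype=np.float64)
    for k in range(n):
        ang = 360.0 * k / n
        if axis is None and order == 1:
            acc += rotate_about_z(v.grid, ang)
        else:
            rot = _Rot.from_rotvec(
                np.deg2rad(ang) * (np.asarray(axis, float) / np.linalg.norm(axis)
                                   if axis is not None
                                   else np.array([0.0, 0.0, 1.0]))
            ).as_matrix()
            acc += rotate_volume(v.grid, rot, order=order)
    return Volume(acc / n, v.pixel_size)


# ---------------------------------------------------------------------------
# iterative refinement
# ---------------------------------------------------------------------------

@dataclass
class RefineConfig:
    """Schedule for alignment-by-classification refinement.

    Round 1 seeds the reference from hierarchical classification of the
    initially posed (spin-unaligned) particles: each class average is
    coherent over the subset of particles whose interface features happen to
    agree, and the most azimuthally structured one becomes the first
    reference. Subsequent rounds alternate global/local spin alignment with
    re-averaging until the mean constrained CC stops improving.
    """

    n_rounds: int = 4
    spin_steps: tuple[float, ...] = (6.0, 3.0, 3.0, 3.0)
    local_window_deg: float = 12.0  # local search half-width after round 1
    n_classes_seed: int = 10
    n_components: int = 8
    focus_radius_nm: float = 25.0
    focus_half_height_nm: float = 6.0
    lowpass_align_nm: float = 4.5  # resolution used during alignment scoring
    epsilon: float = 1e-3


def sphere_mask(box: int, radius_vox: float, soft_vox: float = 1.0) -> np.ndarray:
    ax = np.arange(box) - box // 2
    Z, Y, X = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)
    return np.clip((radius_vox + soft_vox - r) / soft_vox, 0, 1).astype(np.float32)


def cylinder_mask(box: int, radius_vox: float, half_height_vox: float,
                  soft_vox: float = 1.0) -> np.ndarray:
    ax = np.arange(box) - box // 2
    Z, Y, X = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(X**2 + Y**2)
    m_r = np.clip((radius_vox + soft_vox - r) / soft_vox, 0, 1)
    m_z = np.clip((half_height_vox + soft_vox - np.abs(Z)) / soft_vox, 0, 1)
    return (m_r * m_z).astype(np.float32)


def _remove_rotational_mean(grid: np.ndarray, n_steps: int = 24) -> np.ndarray:
    """Subtract the (approximate) rotational mean about z.

    Spin alignment only uses azimuthal structure; the symmetric component
    adds a spin-independent term to every score. More importantly, noise
    aligned against a reference leaves a reference-shaped residue in the
    next average ("ghost" bias), and if the reference's ring peaks sit on a
    radially sloping symmetric background, low-pass blurring drags them
    inward and the bias propagates. Removing the symmetric part *before*
    blurring keeps the reference's azimuthal features at their true radii.
    """
    acc = np.zeros_like(grid, dtype=np.float64)
    for k in range(n_steps):
        acc += rotate_about_z(grid, 360.0 * k / n_steps)
    return grid - (acc / n_steps).astype(grid.dtype)


def _annulus_structure(grid: np.ndarray, nm_vox: float,
                       r_in_nm: float = 10.0, r_out_nm: float = 25.0,
                       half_height_nm: float = 5.0) -> float:
    """Azimuthal (non-rotationally-symmetric) energy in the interface
    annulus; scores how much ring-like structure an average carries."""
    n = grid.shape[0]
    ax = (np.arange(n) - n // 2) * nm_vox
    Z, Y, X = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(X**2 + Y**2)
    sel = (r >= r_in_nm) & (r <= r_out_nm) & (np.abs(Z) <= half_height_nm)
    phi = np.arctan2(Y[sel], X[sel])
    vals = grid[sel]
    nbins = 72
    idx = np.clip(((phi + np.pi) / (2 * np.pi) * nbins).astype(int), 0, nbins - 1)
    prof = np.bincount(idx, weights=vals, minlength=nbins) / \
        np.maximum(np.bincount(idx, minlength=nbins), 1)
    return float(np.var(prof))


def refine(
    subs: list[Volume],
    wedges: list[WedgeMask],
    init_poses: list[Pose],
    config: RefineConfig | None = None,
) -> tuple[ClassAverage, dict]:
    """Alignment-by-classification refinement of a particle pool.

    Returns the final (C1) wedge-compensated average and a history dict with
    per-round mean scores, class sizes and the final per-particle poses.
    """
    from . import tomo

    cfg = config or RefineConfig()
    if len(subs) == 0:
        raise ValueError("empty particle pool")
    box = subs[0].shape[0]
    nm_vox = subs[0].nm_per_voxel

    # bring everything into the docking frame once
    posed = [apply_pose(s, p) for s, p in zip(subs, init_poses)]
    frame_wedges = [w.rotated(p.matrix) for w, p in zip(wedges, init_poses)]

    focus = cylinder_mask(box, cfg.focus_radius_nm / nm_vox,
                          cfg.focus_half_height_nm / nm_vox)

    def lp(vol: Volume) -> Volume:
        if cfg.lowpass_align_nm <= 0:
            return vol
        cutoff = min(1.0 / cfg.lowpass_align_nm, 1.0 / (2 * nm_vox) * 0.999)
        return tomo.lowpass(vol, cutoff)

    posed_lp = [lp(v) for v in posed]

    history: dict = {"rounds": []}

    # --- seed reference by classification of unaligned particles
    n_classes = min(cfg.n_classes_seed, len(subs))
    labels = msa_classify(posed_lp, frame_wedges, cfg.n_components,
                          n_classes, focus)
    id_poses = [Pose() for _ in subs]
    best_struct, seed_ref = -np.inf, None
    class_sizes = []
    for c in range(n_classes):
        members = [i for i in range(len(subs)) if labels[i] == c]
        class_sizes.append(len(members))
        if len(members) < 2:
            continue
        ca = wedge_compensated_average(
            [posed[i] for i in members], [id_poses[i] for i in members],
            [frame_wedges[i] for i in members], members)
        s = _annulus_structure(ca.volume.grid, nm_vox)
        if s > best_struct:
            best_struct, seed_ref = s, ca
    if seed_ref is None:  # all classes degenerate; fall back to global mean
        seed_ref = wedge_compensated_average(posed, id_poses, frame_wedges)
    history["seed_class_sizes"] = class_sizes

    def align_ref(vol: Volume) -> Volume:
        resid = _remove_rotational_mean(vol.grid)
        return lp(Volume(resid, vol.pixel_size))

    ref = align_ref(seed_ref.volume)

    spins = np.zeros(len(subs))
    scores = np.full(len(subs), -np.inf)
    prev_mean = -np.inf
    for rnd in range(cfg.n_rounds):
        step = cfg.spin_steps[min(rnd, len(cfg.spin_steps) - 1)]
        if rnd == 0:
            windows = None
        else:
            windows = [((s - cfg.local_window_deg) % 360.0,
                        (s + cfg.local_window_deg) % 360.0) for s in spins]
        spins, scores = align_spins(posed_lp, frame_wedges, ref, step,
                                    spin_windows=windows, focus_mask=focus)
        poses = [Pose((s, 0.0, 0.0)) for s in spins]
        avg = wedge_compensated_average(posed, poses, frame_wedges)
        ref = align_ref(avg.volume)
        mean_score = float(np.mean(scores[np.isfinite(scores)]))
        history["rounds"].append({
            "round": rnd, "spin_step": step, "mean_score": mean_score,
        })
        if mean_score - prev_mean < cfg.epsilon and rnd > 0:
            break
        prev_mean = mean_score

    final_poses = [p0.compose(Pose((s, 0.0, 0.0)))
                   for p0, s in zip(init_poses, spins)]
    avg = wedge_compensated_average(subs, final_poses, wedges)
    avg.provenance["history"] = history
    avg.provenance["mean_score"] = float(np.mean(scores[np.isfinite(scores)]))
    history["final_spins_deg"] = spins.tolist()
    history["final_scores"] = scores.tolist()
    history["final_poses"] = [
        {"rotation": list(p.rotation), "shift": p.shift.tolist()}
        for p in final_poses
    ]
    return avg, history
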