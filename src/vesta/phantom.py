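"""Synthetic docking-site scenes and cohort generation.

This module emulates the statistical structure of a primary-neuron cryo-ET
study population: ~40-nm spherical bilayer vesicles docked to a planar
presynaptic membrane, with a ring of rod-like protein densities bridging the
interbilayer gap of primed vesicles and disordered tethers on tethered ones.
Scenes are rendered as positive-contrast density volumes (protein/lipid
positive, background exactly zero, the deposited-map sign convention),
projected as an ideal single-axis tilt series, degraded with white noise,
and reconstructed with the missing wedge of the limited tilt range.

Geometry conventions: the vesicle "diameter" follows the bilayer-peak
convention of the census (mid-surface center-to-center distance + 5 nm),
so a vesicle of diameter D has bilayer mid-surface radius (D - 5)/2. The
interbilayer gap g puts the membrane mid-plane at center-to-center distance
g + 5 nm from the vesicle mid-surface. Rod centers sit on a circle of
diameter (ring_outer_diameter - rod radial extent), equally spaced about the
docking axis, and span the gap from the membrane mid-plane to the local
vesicle mid-surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import tomo
from .volume import TiltSeries, Volume

__all__ = [
    "GroundTruthScene",
    "AcquisitionSpec",
    "CohortConfig",
    "make_docked_scene",
    "build_scene_volume",
    "simulate_tilt_series",
    "degrade",
    "generate_cohort",
]

BILAYER_NM = 5.0          # average lipid-bilayer thickness
SOFT_EDGE_VOXELS = 1.0    # linear soft-edge width on every component

DEFAULT_AMPLITUDES = {
    "membrane": 1.0,
    "vesicle": 1.0,
    "rod": 1.5,
    "tether": 1.0,
}


@dataclass
class GroundTruthScene:
    """Parametric truth for one vesicle-membrane-protein phantom.

    Positions are in nm relative to the box center; vectors are physical
    (x, y, z). ``membrane_plane_z`` is the signed offset of the membrane
    mid-plane along ``membrane_normal`` (which points from membrane to
    vesicle).
    """

    vesicle_center: np.ndarray
    vesicle_diameter: float
    interbilayer_gap: float
    membrane_normal: np.ndarray
    membrane_plane_z: float
    bilayer_thickness: float = BILAYER_NM
    n_densities: int = 6
    ring_outer_diameter: float = 38.0
    rod_dims: tuple[float, float, float] = (2.0, 4.0, 8.5)
    ring_phase_deg: float = 0.0
    density_amplitudes: dict = field(default_factory=lambda: dict(DEFAULT_AMPLITUDES))
    docking_state_truth: str = "primed"
    tether_specs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.vesicle_center = np.asarray(self.vesicle_center, dtype=float)
        n = np.asarray(self.membrane_normal, dtype=float)
        nn = np.linalg.norm(n)
        if nn == 0:
            raise ValueError("membrane_normal must be non-zero")
        self.membrane_normal = n / nn
        if not self.vesicle_diameter > 2 * self.bilayer_thickness:
            raise ValueError(
                f"vesicle_diameter {self.vesicle_diameter} must exceed twice the "
                f"bilayer thickness {self.bilayer_thickness}"
            )
        if self.interbilayer_gap < 0:
            raise ValueError("interbilayer_gap must be >= 0")
        if self.n_densities < 0:
            raise ValueError("n_densities must be >= 0")

    @property
    def mid_radius(self) -> float:
        """Bilayer mid-surface radius: (diameter - bilayer thickness) / 2."""
        return (self.vesicle_diameter - self.bilayer_thickness) / 2.0

    @property
    def center_to_center(self) -> float:
        """Vesicle mid-surface to membrane mid-plane distance along the axis."""
        return self.interbilayer_gap + self.bilayer_thickness

    @property
    def ring_radius(self) -> float:
        """Radius of the circle carrying the rod centers."""
        return (self.ring_outer_diameter - self.rod_dims[0]) / 2.0

    def contact_point(self) -> np.ndarray:
        """Point on the membrane mid-plane closest to the vesicle (nm)."""
        return self.vesicle_center - (self.mid_radius + self.center_to_center) * self.membrane_normal

    def rod_centers(self) -> np.ndarray:
        """Analytic rod-center ring positions at the interface mid-height (nm)."""
        n_hat = self.membrane_normal
        u, v = _plane_basis(n_hat)
        phis = np.deg2rad(self.ring_phase_deg + 360.0 / max(self.n_densities, 1)
                          * np.arange(self.n_densities))
        base = self.contact_point() + 0.5 * self.center_to_center * n_hat
        return base[None, :] + self.ring_radius * (
            np.cos(phis)[:, None] * u[None, :] + np.sin(phis)[:, None] * v[None, :]
        )


@dataclass
class AcquisitionSpec:
    """Single-axis acquisition geometry and noise level."""

    pixel_size: float = 21.6  # Å/voxel (bin4 scale of a 5.4-Å acquisition)
    tilt_min: float = -51.0
    tilt_max: float = 51.0
    tilt_step: float = 3.0
    tilt_axis: str = "y"
    snr: float = 2.0  # signal variance / noise variance on each projection
    noise_model: str = "gaussian_white"
    lowpass_cutoff: float | None = None  # 1/nm, applied to the reconstruction
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.tilt_min < 0 < self.tilt_max):
            raise ValueError("tilt range must straddle 0")
        if self.tilt_step <= 0:
            raise ValueError("tilt_step must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.tilt_axis != "y":
            raise ValueError("only the y tilt axis is supported")
        if self.noise_model != "gaussian_white":
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def angles(self) -> np.ndarray:
        return tomo.tilt_angles(self.tilt_min, self.tilt_max, self.tilt_step)


@dataclass
class CohortConfig:
    """Population parameters of a synthetic docking cohort.

    Defaults reproduce the study conditions: diameters 43.88 +/- 5.32 nm,
    ~75% primed (gap <= 6 nm, drawn uniformly around the 3.5-nm mode),
    the remainder tethered at 8-20 nm, six densities on a 38-nm ring.
    """

    n_vesicles: int = 100
    diameter_mean: float = 43.88
    diameter_sd: float = 5.32
    primed_fraction: float = 0.75
    primed_gap_range: tuple[float, float] = (2.0, 5.0)
    tethered_gap_range: tuple[float, float] = (8.0, 20.0)
    view_mix: float = 2556.0 / 7527.0  # probability of a side view
    n_densities: int = 6
    ring_outer_diameter: float = 38.0
    box_size: int = 64
    reconstruction: str = "wbp"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.primed_fraction <= 1:
            raise ValueError("primed_fraction must be in [0, 1]")
        lo, hi = self.primed_gap_range
        if not (0 <= lo <= hi <= 6):
            raise ValueError("primed_gap_range must lie within [0, 6] nm")
        lo, hi = self.tethered_gap_range
        if not (8 <= lo <= hi <= 20):
            raise ValueError("tethered_gap_range must lie within [8, 20] nm")
        if not 0 <= self.view_mix <= 1:
            raise ValueError("view_mix must be in [0, 1]")


def _plane_basis(n_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Right-handed orthonormal basis (u, v) of the plane normal to n_hat."""
    ref = np.array([0.0, 0.0, 1.0])
    if abs(n_hat @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    u = np.cross(ref, n_hat)
    u /= np.linalg.norm(u)
    v = np.cross(n_hat, u)
    return u, v


def make_docked_scene(
    diameter: float = 43.88,
    gap: float = 3.5,
    view: str = "side",
    normal_azimuth_deg: float = 0.0,
    normal_sign: int = 1,
    docking_state: str = "primed",
    n_densities: int = 6,
    ring_outer_diameter: float = 38.0,
    ring_phase_deg: float = 0.0,
    tether_specs: list | None = None,
    amplitudes: dict | None = None,
) -> GroundTruthScene:
    """Build a geometrically consistent docked scene centered in the box.

    ``view='side'`` puts the membrane normal in the beam-perpendicular plane
    at the given azimuth; ``view='top_bottom'`` aligns it with the beam
    (sign +1: membrane below the vesicle at low z).
    """
    if view == "side":
        psi = np.deg2rad(normal_azimuth_deg)
        n_hat = np.array([np.cos(psi), np.sin(psi), 0.0])
    elif view == "top_bottom":
        n_hat = np.array([0.0, 0.0, float(normal_sign)])
    else:
        raise ValueError(f"unknown view {view!r}")
    r_mid = (diameter - BILAYER_NM) / 2.0
    c2c = gap + BILAYER_NM
    return GroundTruthScene(
        vesicle_center=np.zeros(3),
        vesicle_diameter=diameter,
        interbilayer_gap=gap,
        membrane_normal=n_hat,
        membrane_plane_z=-(r_mid + c2c),
        n_densities=n_densities,
        ring_outer_diameter=ring_outer_diameter,
        ring_phase_deg=ring_phase_deg,
        docking_state_truth=docking_state,
        tether_specs=list(tether_specs or []),
        density_amplitudes=dict(amplitudes or DEFAULT_AMPLITUDES),
    )


_COORD_CACHE: dict[tuple, tuple] = {}


def _coords_nm(box_size: int, nm_vox: float):
    key = (box_size, round(nm_vox, 9))
    hit = _COORD_CACHE.get(key)
    if hit is None:
        ax = (np.arange(box_size) - box_size // 2) * nm_vox
        Z, Y, X = np.meshgrid(ax, ax, ax, indexing="ij")
        hit = (X.astype(np.float32), Y.astype(np.float32), Z.astype(np.float32))
        _COORD_CACHE[key] = hit
    return hit


def _soft_profile(signed_dist: np.ndarray, edge_nm: float) -> np.ndarray:
    """1 deep inside (signed_dist << 0), 0 outside, linear ramp of width edge_nm."""
    return np.clip(0.5 - signed_dist / edge_nm, 0.0, 1.0)


def build_scene_volume(
    scene: GroundTruthScene, box_size: int, pixel_size: float
) -> Volume:
    """Render a noise-free density volume of the scene (protein/lipid positive,
    background exactly 0)."""
    nm_vox = pixel_size / 10.0
    half_nm = (box_size // 2) * nm_vox
    edge = SOFT_EDGE_VOXELS * nm_vox
    r_out = scene.mid_radius + scene.bilayer_thickness / 2.0 + edge
    for axis, c in zip("xyz", scene.vesicle_center):
        if abs(c) + r_out > 0.9 * half_nm:
            raise ValueError(
                f"vesicle (outer radius {r_out:.1f} nm) exceeds the box along "
                f"{axis} (10% margin of half-box {half_nm:.1f} nm)"
            )
    # a membrane plane beyond the box simply falls outside the field of view
    # and renders as nothing (used e.g. for bare-shell reference scenes)

    X, Y, Z = _coords_nm(box_size, nm_vox)
    amps = {**DEFAULT_AMPLITUDES, **scene.density_amplitudes}
    nx, ny, nz = scene.membrane_normal
    cx, cy, cz = scene.vesicle_center
    t = X * nx + Y * ny + Z * nz  # coordinate along the membrane normal
    out = np.zeros_like(X)

    # planar membrane slab
    d_plane = np.abs(t - scene.membrane_plane_z) - scene.bilayer_thickness / 2.0
    out += amps["membrane"] * _soft_profile(d_plane, edge)

    # vesicle bilayer shell
    r = np.sqrt((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2)
    d_shell = np.abs(r - scene.mid_radius) - scene.bilayer_thickness / 2.0
    out += amps["vesicle"] * _soft_profile(d_shell, edge)

    def _segment_bbox(p0: np.ndarray, p1: np.ndarray, pad_nm: float):
        """Voxel-index slices of the axis-aligned box around segment p0-p1."""
        lo = np.minimum(p0, p1) - pad_nm
        hi = np.maximum(p0, p1) + pad_nm
        sl = []
        for axis in (2, 1, 0):  # z, y, x in array order
            a0 = int(np.floor(lo[axis] / nm_vox)) + box_size // 2
            a1 = int(np.ceil(hi[axis] / nm_vox)) + box_size // 2 + 1
            sl.append(slice(max(a0, 0), min(a1, box_size)))
        return tuple(sl)

    # interface rods on the ring
    if scene.n_densities > 0:
        u, v = _plane_basis(scene.membrane_normal)
        c_perp = scene.vesicle_center - (scene.vesicle_center @ scene.membrane_normal) * scene.membrane_normal
        t_c = scene.vesicle_center @ scene.membrane_normal
        rad_half = scene.rod_dims[0] / 2.0
        tan_half = scene.rod_dims[1] / 2.0
        rho = scene.ring_radius
        # axial span: membrane mid-plane up to the local vesicle mid-surface
        if rho < scene.mid_radius:
            t_top = t_c - np.sqrt(scene.mid_radius**2 - rho**2)
        else:
            t_top = scene.membrane_plane_z + scene.rod_dims[2]
        n_hat = scene.membrane_normal
        # anti-aliased cross-section: the nominal rod widths are below the
        # voxel size, and a hard-edged sub-Nyquist feature voxelizes with a
        # lattice-dependent apparent position (up to half a voxel). Gaussian
        # profiles with sigma floored at 0.6 voxel are band-limited enough
        # that the sampled blob carries its true sub-voxel center.
        sig_rad = max(rad_half / 1.7, 0.8 * nm_vox)
        sig_tan = max(tan_half / 1.7, 0.8 * nm_vox)
        reach = 3.0 * max(sig_rad, sig_tan)
        for k in range(scene.n_densities):
            phi = np.deg2rad(scene.ring_phase_deg + k * 360.0 / scene.n_densities)
            off = c_perp + rho * (np.cos(phi) * u + np.sin(phi) * v)
            p0 = off + scene.membrane_plane_z * n_hat
            p1 = off + t_top * n_hat
            sl = _segment_bbox(p0, p1, reach + edge)
            Xs, Ys, Zs = X[sl], Y[sl], Z[sl]
            pu = Xs * u[0] + Ys * u[1] + Zs * u[2] - c_perp @ u
            pv = Xs * v[0] + Ys * v[1] + Zs * v[2] - c_perp @ v
            ts = Xs * n_hat[0] + Ys * n_hat[1] + Zs * n_hat[2]
            d_rad = pu * np.cos(phi) + pv * np.sin(phi) - rho
            d_tan = -pu * np.sin(phi) + pv * np.cos(phi)
            cross = np.exp(-0.5 * ((d_rad / sig_rad) ** 2
                                   + (d_tan / sig_tan) ** 2))
            ax = np.maximum(scene.membrane_plane_z - ts, ts - t_top)
            out[sl] += amps["rod"] * cross * _soft_profile(ax, edge)

    # disordered tethers (tethered scenes)
    if scene.tether_specs:
        u, v = _plane_basis(scene.membrane_normal)
        n_hat = scene.membrane_normal
        for anchor_angle, length in scene.tether_specs:
            phi = np.deg2rad(anchor_angle)
            # anchor on the lower vesicle mid-surface, 25 deg off the docking axis
            pol = np.deg2rad(25.0)
            anchor = scene.vesicle_center + scene.mid_radius * (
                -np.cos(pol) * n_hat
                + np.sin(pol) * (np.cos(phi) * u + np.sin(phi) * v)
            )
            seg = -n_hat  # directed toward the membrane
            sl = _segment_bbox(anchor, anchor + length * seg, 1.0 + 2 * edge)
            Xs, Ys, Zs = X[sl], Y[sl], Z[sl]
            px_, py_, pz_ = Xs - anchor[0], Ys - anchor[1], Zs - anchor[2]
            s = np.clip(px_ * seg[0] + py_ * seg[1] + pz_ * seg[2], 0.0, length)
            dx = px_ - s * seg[0]
            dy = py_ - s * seg[1]
            dz = pz_ - s * seg[2]
            d_seg = np.sqrt(dx**2 + dy**2 + dz**2) - 1.0  # 1-nm tether radius
            out[sl] += amps["tether"] * _soft_profile(d_seg, edge)

    return Volume(out, pixel_size)


def simulate_tilt_series(volume: Volume, acq: AcquisitionSpec) -> TiltSeries:
    """Project a cubic volume at every stage tilt of the acquisition scheme."""
    return tomo.project(volume, acq.angles())


def degrade(tilt: TiltSeries, snr: float, seed: int) -> TiltSeries:
    """Add zero-mean white noise per projection at variance = signal var / snr."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    out = tilt.projections.copy()
    for i in range(len(out)):
        var = float(out[i].var())
        sigma = np.sqrt(var / snr) if var > 0 else 0.0
        out[i] += rng.standard_normal(out[i].shape).astype(np.float32) * sigma
    return TiltSeries(out, tilt.tilt_angles.copy(), tilt.pixel_size)


def _reconstruct(tilt: TiltSeries, how: str) -> Volume:
    if how == "wbp":
        return tomo.reconstruct_wbp(tilt)
    if how == "sirt":
        return tomo.reconstruct_sirt(tilt)
    raise ValueError(f"unknown reconstruction {how!r}")


def simulate_subtomogram(
    scene: GroundTruthScene, acq: AcquisitionSpec, box_size: int,
    noise_seed: int, reconstruction: str = "wbp",
) -> Volume:
    """Scene -> tilt series -> noise -> missing-wedge reconstruction."""
    vol = build_scene_volume(scene, box_size, acq.pixel_size)
    tilt = simulate_tilt_series(vol, acq)
    tilt = degrade(tilt, acq.snr, noise_seed)
    rec = _reconstruct(tilt, reconstruction)
    if acq.lowpass_cutoff is not None:
        rec = tomo.lowpass(rec, acq.lowpass_cutoff)
    return rec


def generate_cohort(
    cfg: CohortConfig,
    acq: AcquisitionSpec,
    permissive: bool = False,
) -> tuple[list[Volume], pd.DataFrame]:
    """Sample a cohort of docked vesicles and simulate their subtomograms.

    Returns the subtomogram volumes and a truth table (one row per vesicle)
    recording every sampled parameter. Fully reproducible from cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    subtomos: list[Volume] = []
    rows: list[dict] = []
    nm_vox = acq.pixel_size / 10.0
    center_vox = cfg.box_size // 2

    for i in range(cfg.n_vesicles):
        # truncated-normal diameter: reject non-physical draws
        while True:
            diameter = rng.normal(cfg.diameter_mean, cfg.diameter_sd)
            if diameter > 2 * BILAYER_NM + 1.0:
                break
        primed = rng.random() < cfg.primed_fraction
        if primed:
            gap = rng.uniform(*cfg.primed_gap_range)
            state = "primed"
        else:
            gap = rng.uniform(*cfg.tethered_gap_range)
            state = "tethered"
        side = rng.random() < cfg.view_mix
        view = "side" if side else "top_bottom"
        azimuth = rng.uniform(0.0, 360.0)
        normal_sign = 1 if rng.random() < 0.5 else -1
        ring_phase = rng.uniform(0.0, 360.0)
        if primed:
            tethers: list = []
            n_rods = cfg.n_densities
        else:
            n_rods = 0
            n_teth = int(rng.integers(2, 6))
            tethers = [(float(rng.uniform(0, 360)), float(gap + BILAYER_NM))
                       for _ in range(n_teth)]
        noise_seed = int(rng.integers(0, 2**31 - 1))
        try:
            scene = make_docked_scene(
                diameter=diameter, gap=gap, view=view,
                normal_azimuth_deg=azimuth, normal_sign=normal_sign,
                docking_state=state, n_densities=n_rods,
                ring_outer_diameter=cfg.ring_outer_diameter,
                ring_phase_deg=ring_phase, tether_specs=tethers,
            )
            sub = simulate_subtomogram(
                scene, acq, cfg.box_size, noise_seed, cfg.reconstruction
            )
        except ValueError as exc:
            if permissive:
                continue
            raise ValueError(f"vesicle {i}: {exc}") from exc
        contact_vox = center_vox + scene.contact_point() / nm_vox
        n_hat = scene.membrane_normal
        subtomos.append(sub)
        rows.append({
            "id": i,
            "view": view,
            "docking_state": state,
            "diameter_nm": diameter,
            "gap_nm": gap,
            "c2c_nm": gap + BILAYER_NM,
            "ring_phase_deg": ring_phase,
            "n_densities": n_rods,
            "ring_outer_diameter_nm": cfg.ring_outer_diameter,
            "normal_x": n_hat[0], "normal_y": n_hat[1], "normal_z": n_hat[2],
            "center_x_vox": center_vox, "center_y_vox": center_vox,
            "center_z_vox": center_vox,
            "contact_x_vox": contact_vox[0], "contact_y_vox": contact_vox[1],
            "contact_z_vox": contact_vox[2],
            "n_tethers": len(tethers),
            "noise_seed": noise_seed,
            "snr": acq.snr,
            "pixel_size_A": acq.pixel_size,
        })
    return subtomos, pd.DataFrame(rows)
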