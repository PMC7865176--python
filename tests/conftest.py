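"""Shared fixtures: small synthetic scenes and cohorts.

Fixtures use a coarse 32-voxel box at 43.2 Å/voxel (same 138-nm physical
field as the production 64-voxel box) wherever the check is geometric, and
the production scale only where sub-voxel accuracy is under test.
"""

from __future__ import annotations

import numpy as np
import pytest

from vesta import sta, tomo
from vesta.phantom import (AcquisitionSpec, CohortConfig, build_scene_volume,
                           generate_cohort, make_docked_scene,
                           simulate_tilt_series)
from vesta.transform import fourier_shift
from vesta.volume import Volume

PIX_BIN4 = 21.6  # Å/voxel


@pytest.fixture(scope="session")
def acq() -> AcquisitionSpec:
    return AcquisitionSpec()


@pytest.fixture(scope="session")
def default_scene():
    """Noise-free default primed scene (6 rods, 38-nm ring, 3.5-nm gap),
    side view."""
    return make_docked_scene(view="side", normal_azimuth_deg=40.0,
                             ring_phase_deg=25.0)


@pytest.fixture(scope="session")
def default_scene_volume(default_scene, acq):
    return build_scene_volume(default_scene, 64, acq.pixel_size)


def docking_frame_volume(gap=3.5, n_densities=6, ring=38.0, phase=25.0,
                         diameter=43.88, box=64, pixel=PIX_BIN4):
    """Noise-free phantom in the docking frame: axis = z, membrane above,
    docking midpoint at the box center (the frame of refined averages)."""
    sc = make_docked_scene(view="top_bottom", normal_sign=-1, gap=gap,
                           n_densities=n_densities, ring_outer_diameter=ring,
                           ring_phase_deg=phase, diameter=diameter)
    mid = sc.contact_point() + 0.5 * sc.center_to_center * sc.membrane_normal
    vol = build_scene_volume(sc, box, pixel)
    g = fourier_shift(vol.grid, -mid[::-1] / (pixel / 10.0))
    return Volume(g, pixel), sc


@pytest.fixture(scope="session")
def docking_frame_default():
    return docking_frame_volume()


@pytest.fixture(scope="session")
def sphere_volume():
    """Uniform solid sphere, compactly supported: projection oracle."""
    n = 32
    ax = np.arange(n) - n // 2
    Z, Y, X = np.meshgrid(ax, ax, ax, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)
    # 2-voxel soft edge: band-limited enough for interpolation-based projectors
    g = np.clip((10.0 - r) / 2.0, 0, 1).astype(np.float32)
    return Volume(g, PIX_BIN4)


@pytest.fixture(scope="session")
def small_cohort(acq):
    """Mixed-view noisy cohort of 24 vesicles at production scale."""
    cfg = CohortConfig(n_vesicles=24, seed=11, view_mix=0.5)
    subs, truth = generate_cohort(cfg, acq)
    return subs, truth, cfg


@pytest.fixture(scope="session")
def reconstructed_default(default_scene, default_scene_volume, acq):
    """Noise-free WBP reconstruction of the default side-view scene."""
    tilt = simulate_tilt_series(default_scene_volume, acq)
    return tomo.reconstruct_wbp(tilt), default_scene
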