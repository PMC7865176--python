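"""Wedge masks, constrained CC, poses, alignment, classification,
averaging and symmetrization."""

import numpy as np
import pytest

from vesta import sta, tomo
from vesta.phantom import (AcquisitionSpec, CohortConfig, build_scene_volume,
                           generate_cohort, make_docked_scene)
from vesta.volume import Volume

from conftest import docking_frame_volume


class TestWedgeMask:
    def test_full_range_is_all_ones(self):
        m = sta.make_wedge_mask((16, 16, 16), -90, 90).array()
        np.testing.assert_array_equal(m, 1.0)

    def test_covered_fraction_matches_solid_angle(self):
        wm = sta.make_wedge_mask((64, 64, 64), -51, 51)
        assert wm.covered_fraction() == pytest.approx(102 / 180, rel=0.02)

    def test_hermitian_symmetry_even_under_negation(self):
        rng = np.random.default_rng(0)
        from scipy.spatial.transform import Rotation
        rot = Rotation.random(random_state=1).as_matrix()
        m = sta.make_wedge_mask((16, 16, 16), -51, 51, orientation=rot).array()
        flipped = np.roll(m[::-1, ::-1, ::-1], 1, axis=(0, 1, 2))
        np.testing.assert_array_equal(m, flipped)

    def test_angles_beyond_90_rejected(self):
        with pytest.raises(ValueError):
            sta.make_wedge_mask((8, 8, 8), -95, 51)
        with pytest.raises(ValueError):
            sta.make_wedge_mask((8, 8, 8), 10, 51)


class TestConstrainedCC:
    def test_self_correlation_is_one(self):
        x = np.random.default_rng(1).standard_normal((16, 16, 16))
        assert sta.constrained_cc(x, x) == pytest.approx(1.0)

    def test_anticorrelation_is_minus_one(self):
        x = np.random.default_rng(2).standard_normal((16, 16, 16))
        assert sta.constrained_cc(x, -x) == pytest.approx(-1.0)

    def test_parseval_equivalence_with_brute_force(self):
        # wedge-masked Fourier CC == direct-space correlation of the
        # M-filtered, mean-subtracted volumes
        rng = np.random.default_rng(3)
        wa = sta.make_wedge_mask((32, 32, 32), -51, 51)
        from scipy.spatial.transform import Rotation
        wb = sta.make_wedge_mask(
            (32, 32, 32), -60, 45,
            orientation=Rotation.random(random_state=7).as_matrix())
        for trial in range(20):
            x = rng.standard_normal((32, 32, 32))
            y = rng.standard_normal((32, 32, 32))
            M = wa.array() * wb.array()
            M.flat[0] = 0.0
            xf = np.real(np.fft.ifftn(np.fft.fftn(x) * M))
            yf = np.real(np.fft.ifftn(np.fft.fftn(y) * M))
            brute = np.sum(xf * yf) / np.sqrt(np.sum(xf**2) * np.sum(yf**2))
            assert sta.constrained_cc(x, y, wa, wb) == pytest.approx(
                brute, abs=1e-6)

    def test_flat_volume_gives_undefined_score(self):
        x = np.random.default_rng(4).standard_normal((16, 16, 16))
        with pytest.raises(sta.UndefinedScoreError):
            sta.constrained_cc(np.zeros((16, 16, 16)), x)


class TestPose:
    def test_axis_already_z_gives_identity_rotation(self):
        p = sta.init_pose(np.array([32.0, 32, 32]), np.array([32.0, 32, 45]), 64)
        np.testing.assert_allclose(p.matrix, np.eye(3), atol=1e-12)

    def test_axis_along_x_rotates_slab_normal_to_z(self, acq):
        # membrane with normal -x; after init pose the slab must be normal z
        sc = make_docked_scene(view="side", normal_azimuth_deg=180.0, gap=3.5)
        vol = build_scene_volume(sc, 64, acq.pixel_size)
        center = np.array([32.0, 32.0, 32.0])
        contact = center + sc.contact_point() / vol.nm_per_voxel
        pose = sta.init_pose(center, contact, 64,
                             sc.mid_radius / vol.nm_per_voxel)
        framed = sta.apply_pose(vol, pose)
        # density profile along z must now show the membrane slab peak
        prof = framed.grid.mean(axis=(1, 2))
        zc = np.argmax(prof)
        z_nm = (zc - 32) * vol.nm_per_voxel
        assert 0 < z_nm < 10  # membrane just above the centered midpoint

    def test_pose_then_inverse_recovers_volume(self, acq):
        sc = make_docked_scene(view="side", normal_azimuth_deg=40.0)
        vol = build_scene_volume(sc, 64, acq.pixel_size)
        pose = sta.Pose((30.0, 45.0, -20.0), np.array([1.0, -2.0, 0.5]))
        inv = sta.Pose.from_matrix(pose.matrix.T,
                                   -(pose.matrix.T @ pose.shift))
        back = sta.apply_pose(sta.apply_pose(vol, pose), inv)
        core = (slice(12, 52),) * 3
        err = np.sqrt(np.mean((back.grid[core] - vol.grid[core]) ** 2))
        # two linear resamplings blur the 1-voxel rods; interpolation
        # tolerance declared at 30% RMS of the core signal
        assert err < 0.3 * np.sqrt(np.mean(vol.grid[core] ** 2))

    def test_zero_docking_vector_rejected(self):
        with pytest.raises(ValueError):
            sta.init_pose(np.zeros(3), np.zeros(3), 64)


class TestAlignOne:
    def test_self_alignment_is_identity_with_score_one(self):
        vol, _ = docking_frame_volume(box=32, pixel=43.2)
        wedge = sta.make_wedge_mask((32, 32, 32), -90, 90)
        pose, score = sta.align_one(vol, wedge, vol, spin_step=30.0)
        assert score == pytest.approx(1.0, abs=1e-3)
        assert pose.rotation[0] % 360 == pytest.approx(0.0, abs=1e-6)

    def test_planted_spin_recovered_within_grid_step(self):
        # asymmetric phantom (single interface rod) planted at 24 deg;
        # alignment scored inside the interface focus at alignment resolution,
        # as the refinement loop does
        ref, _ = docking_frame_volume(phase=0.0, n_densities=1)
        rot, _ = docking_frame_volume(phase=24.0, n_densities=1)
        ref_lp = tomo.lowpass(ref, 1 / 6.0)
        rot_lp = tomo.lowpass(rot, 1 / 6.0)
        wedge = sta.make_wedge_mask((64, 64, 64), -51, 51)
        focus = sta.cylinder_mask(64, 25 / 2.16, 6 / 2.16)
        pose, score = sta.align_one(rot_lp, wedge, ref_lp, spin_step=3.0,
                                    focus_mask=focus)
        # contract: applying the pose brings the rod onto the reference rod
        aligned = sta.apply_pose(rot, pose)
        plane = aligned.grid[28:37].mean(axis=0)
        iy, ix = np.unravel_index(np.argmax(plane), plane.shape)
        azim = np.rad2deg(np.arctan2(iy - 32, ix - 32)) % 360
        ref_plane = ref.grid[28:37].mean(axis=0)
        jy, jx = np.unravel_index(np.argmax(ref_plane), ref_plane.shape)
        ref_azim = np.rad2deg(np.arctan2(jy - 32, jx - 32)) % 360
        delta = abs((azim - ref_azim + 180) % 360 - 180)
        assert delta <= 4.0  # one grid step plus peak-pixel quantization

    def test_best_score_at_least_initial_score(self):
        rng = np.random.default_rng(8)
        vol, _ = docking_frame_volume(box=32, pixel=43.2, phase=40.0)
        noisy = Volume(vol.grid + 0.5 * rng.standard_normal(vol.shape)
                       .astype(np.float32), vol.pixel_size)
        ref, _ = docking_frame_volume(box=32, pixel=43.2, phase=0.0)
        wedge = sta.make_wedge_mask((32, 32, 32), -51, 51)
        init_score = sta.constrained_cc(noisy, ref, wedge)
        _, best = sta.align_one(noisy, wedge, ref, spin_step=10.0)
        assert best >= init_score - 1e-9


class TestClassification:
    @pytest.fixture(scope="class")
    def two_populations(self):
        """Aligned particles with vs without interface rods, snr 2.

        msa_classify's contract is a common aligned frame, so the rod ring
        carries one phase across the population."""
        rng = np.random.default_rng(5)
        subs, labels = [], []
        for i in range(16):
            n_rods = 6 if i % 2 == 0 else 0
            vol, _ = docking_frame_volume(n_densities=n_rods, phase=20.0)
            g = vol.grid + (np.sqrt(vol.grid.var() / 2.0)
                            * rng.standard_normal(vol.shape)).astype(np.float32)
            subs.append(Volume(g, vol.pixel_size))
            labels.append(i % 2)
        return subs, np.array(labels)

    def test_planted_populations_separated_perfectly(self, two_populations):
        subs, truth = two_populations
        wedges = [sta.make_wedge_mask((64, 64, 64), -51, 51) for _ in subs]
        mask = sta.cylinder_mask(64, 25 / 2.16, 6 / 2.16)
        labels = sta.msa_classify(subs, wedges, n_components=4, n_classes=2,
                                  mask=mask)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(truth, labels) == pytest.approx(1.0)

    def test_single_class_collapses_all_labels(self, two_populations):
        subs, _ = two_populations
        labels = sta.msa_classify(subs, None, n_classes=1)
        assert set(labels) == {0}

    def test_more_classes_than_particles_rejected(self, two_populations):
        subs, _ = two_populations
        with pytest.raises(ValueError):
            sta.msa_classify(subs[:3], None, n_classes=5)

    def test_duplication_leaves_partition_structure(self, two_populations):
        subs, truth = two_populations
        wedges = [sta.make_wedge_mask((64, 64, 64), -51, 51) for _ in subs]
        mask = sta.cylinder_mask(64, 25 / 2.16, 6 / 2.16)
        lab1 = sta.msa_classify(subs, wedges, 4, 2, mask)
        lab2 = sta.msa_classify(subs + subs, wedges + wedges, 4, 2, mask)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(np.tile(lab1, 2), lab2) == pytest.approx(1.0)


class TestAveraging:
    def test_single_particle_full_wedge_is_identity(self):
        vol, _ = docking_frame_volume(box=32, pixel=43.2)
        wedge = sta.make_wedge_mask((32, 32, 32), -90, 90)
        avg = sta.wedge_compensated_average([vol], [sta.Pose()], [wedge])
        np.testing.assert_allclose(avg.volume.grid, vol.grid, atol=1e-4)
        assert avg.uncovered_fraction() == 0.0

    def test_average_of_x_and_minus_x_is_zero(self):
        vol, _ = docking_frame_volume(box=32, pixel=43.2)
        neg = Volume(-vol.grid, vol.pixel_size)
        wedge = sta.make_wedge_mask((32, 32, 32), -90, 90)
        avg = sta.wedge_compensated_average([vol, neg],
                                            [sta.Pose(), sta.Pose()],
                                            [wedge, wedge])
        assert np.abs(avg.volume.grid).max() < 1e-5

    def test_known_spins_recover_phantom_and_fill_wedge(self):
        # copies at random known spins about z: average ~ phantom, and the
        # union of the rotated wedges shrinks the uncovered fraction
        rng = np.random.default_rng(9)
        base, _ = docking_frame_volume(phase=0.0)
        wedge = sta.make_wedge_mask((64, 64, 64), -51, 51)
        single_uncovered = 1.0 - wedge.covered_fraction()
        subs, poses, wedges = [], [], []
        half = wedge.array(half=True)
        for _ in range(8):
            spin = float(rng.uniform(0, 360))
            rotated = sta.rotate_about_z(base.grid, spin)
            # observed data only contain the wedge-sampled Fourier region
            observed = np.fft.irfftn(np.fft.rfftn(rotated) * half,
                                     s=rotated.shape, axes=(0, 1, 2))
            subs.append(Volume(observed, base.pixel_size))
            poses.append(sta.Pose((-spin, 0.0, 0.0)))
            wedges.append(wedge)
        avg = sta.wedge_compensated_average(subs, poses, wedges)
        # coverage union: spins about z fill everything except the double
        # cone around kz, so the uncovered fraction shrinks below a single
        # particle's wedge
        assert avg.uncovered_fraction() < single_uncovered
        # the average equals the phantom restricted to the covered union
        union = (avg.wedge_coverage > 0).astype(np.float32)
        base_u = np.fft.irfftn(np.fft.rfftn(base.grid) * union,
                               s=base.grid.shape, axes=(0, 1, 2))
        core = (slice(16, 48),) * 3
        err = np.sqrt(np.mean((avg.volume.grid[core] - base_u[core]) ** 2))
        # linear-interpolation attenuation of each rotated copy leaves a
        # ~30% RMS floor on the 1-voxel-scale features
        assert err < 0.35 * np.sqrt(np.mean(base_u[core] ** 2))

    def test_empty_member_list_rejected(self):
        with pytest.raises(ValueError):
            sta.wedge_compensated_average([], [], [])


class TestSymmetry:
    def test_c1_is_identity(self):
        vol, _ = docking_frame_volume(box=32, pixel=43.2)
        out = sta.apply_cn_symmetry(vol, 1)
        np.testing.assert_array_equal(out.grid, vol.grid)

    def test_idempotence(self):
        vol, _ = docking_frame_volume(phase=10.0)
        once = sta.apply_cn_symmetry(vol, 6)
        twice = sta.apply_cn_symmetry(once, 6)
        rms = np.sqrt(np.mean((twice.grid - once.grid) ** 2))
        assert rms < 0.15 * np.sqrt(np.mean(once.grid**2))

    def test_c6_preserves_sixfold_phantom(self):
        vol, _ = docking_frame_volume(phase=5.0)
        sym = sta.apply_cn_symmetry(vol, 6)
        rms = np.sqrt(np.mean((sym.grid - vol.grid) ** 2))
        assert rms < 0.3 * np.sqrt(np.mean(vol.grid**2))

    def test_symmetrization_reduces_rotational_variance(self):
        # variance over the Cn orbit never increases after symmetrizing
        vol, _ = docking_frame_volume(phase=13.0, n_densities=5)
        sym = sta.apply_cn_symmetry(vol, 6)

        def orbit_var(v):
            stack = np.stack([sta.rotate_about_z(v.grid, 360 * k / 6)
                              for k in range(6)])
            return float(stack.var(axis=0).mean())

        assert orbit_var(sym) <= orbit_var(vol)

    def test_invalid_order_rejected(self):
        vol, _ = docking_frame_volume(box=32, pixel=43.2)
        with pytest.raises(ValueError):
            sta.apply_cn_symmetry(vol, 0)


class TestRefine:
    def test_refinement_is_deterministic(self):
        acq = AcquisitionSpec(snr=1.0)
        cfg = CohortConfig(n_vesicles=10, seed=77, primed_fraction=1.0,
                           box_size=32)
        acq32 = AcquisitionSpec(snr=1.0, pixel_size=43.2)
        subs, truth = generate_cohort(cfg, acq32)
        wedges = [sta.make_wedge_mask((32,) * 3, -51, 51) for _ in subs]
        nm_vox = 4.32
        poses = [sta.init_pose(
            np.array([r.center_x_vox, r.center_y_vox, r.center_z_vox]),
            np.array([r.contact_x_vox, r.contact_y_vox, r.contact_z_vox]),
            32, (r.diameter_nm - 5) / 2 / nm_vox)
            for _, r in truth.iterrows()]
        rc = sta.RefineConfig(n_rounds=2, n_classes_seed=4)
        avg_a, hist_a = sta.refine(subs, wedges, poses, rc)
        avg_b, hist_b = sta.refine(subs, wedges, poses, rc)
        np.testing.assert_array_equal(avg_a.volume.grid, avg_b.volume.grid)
        assert hist_a["final_spins_deg"] == hist_b["final_spins_deg"]
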