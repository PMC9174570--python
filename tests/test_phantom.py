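"""Phantom generators: closed-form ground truth, determinism, noise."""

import numpy as np
import pytest

import dissectflow as df
from dissectflow.fields import LABELS
from dissectflow.phantom import expected_stasis_pct


class TestTubePhantom:
    def test_steady_flow_matches_poiseuille_integral(self, tube):
        _, _, gt = tube
        # Q = v_peak * pi R^2 / 2 for R=10 mm, v_peak=1 m/s
        assert gt.flow_mls["true_lumen"] == pytest.approx(157.0796, abs=1e-3)

    def test_zero_peak_velocity_gives_zero_field_and_full_stasis(self):
        spec = df.PhantomSpec(peak_velocity_ms=0.0, length_mm=40.0)
        fld, mask, gt = df.make_tube_phantom(spec)
        assert np.all(fld.values == 0.0)
        assert np.all(gt.flow_mls["true_lumen"] == 0.0)
        assert gt.stasis_pct["true_lumen"] == 100.0

    def test_symmetric_sinusoid_balances_forward_and_reverse(self):
        spec = df.PhantomSpec(waveform="sinusoid", length_mm=40.0)
        _, _, gt = df.make_tube_phantom(spec)
        assert gt.forward_ml["true_lumen"] == pytest.approx(
            -gt.reverse_ml["true_lumen"])
        assert gt.net_ml["true_lumen"] == pytest.approx(0.0, abs=1e-9)

    def test_underresolved_radius_rejected(self):
        spec = df.PhantomSpec(radius_mm=4.0, spacing_mm=2.5)
        with pytest.raises(df.SizingError):
            df.make_tube_phantom(spec)

    def test_ground_truth_matches_numerical_flux_within_2pct(self, tube):
        fld, mask, gt = tube
        # direct voxel-sum flux through a mid-tube z-plane
        k = fld.grid_shape[2] // 2
        vz = fld.values[:, :, k, 2, 0]
        lum = mask.labels[:, :, k] > 0
        q_num = float(np.sum(vz[lum]) * np.prod(fld.spacing[:2]))
        assert q_num == pytest.approx(gt.flow_mls["true_lumen"][0], rel=0.02)

    def test_mass_consistency_along_tube(self, tube):
        fld, mask, _ = tube
        area = float(np.prod(fld.spacing[:2]))
        qs = []
        for k in range(4, fld.grid_shape[2] - 4, 8):
            lum = mask.labels[:, :, k] > 0
            qs.append(float(np.sum(fld.values[:, :, k, 2, 0][lum]) * area))
        assert (max(qs) - min(qs)) / np.mean(qs) < 0.02

    def test_determinism_byte_identical(self):
        spec = df.PhantomSpec(noise_sd_ms=0.1, seed=42, length_mm=40.0)
        f1, m1, _ = df.make_tube_phantom(spec)
        f2, m2, _ = df.make_tube_phantom(df.PhantomSpec(noise_sd_ms=0.1,
                                                        seed=42,
                                                        length_mm=40.0))
        assert f1.values.tobytes() == f2.values.tobytes()
        assert m1.labels.tobytes() == m2.labels.tobytes()

    def test_different_seed_changes_noise(self):
        a = df.make_tube_phantom(df.PhantomSpec(noise_sd_ms=0.1, seed=1,
                                                length_mm=40.0))[0]
        b = df.make_tube_phantom(df.PhantomSpec(noise_sd_ms=0.1, seed=2,
                                                length_mm=40.0))[0]
        assert not np.array_equal(a.values, b.values)


class TestHelicalPhantom:
    def test_mean_helicity_is_twice_omega_times_axial(self, helical):
        _, _, gt = helical
        assert gt.helicity_density_ms2 == pytest.approx(5.0)

    def test_mirrored_rotation_flips_sign(self):
        spec = df.PhantomSpec(angular_velocity_rads=-5.0,
                              peak_velocity_ms=0.5, n_phases=1,
                              length_mm=40.0)
        _, _, gt = df.make_helical_phantom(spec)
        assert gt.helicity_density_ms2 == pytest.approx(-5.0)

    def test_no_rotation_no_helicity(self):
        spec = df.PhantomSpec(angular_velocity_rads=0.0, n_phases=1,
                              length_mm=40.0)
        _, _, gt = df.make_helical_phantom(spec)
        assert gt.helicity_density_ms2 == 0.0

    def test_venc_violation_warns(self):
        spec = df.PhantomSpec(angular_velocity_rads=200.0, venc_cms=80.0,
                              n_phases=1, length_mm=40.0)
        with pytest.warns(UserWarning, match="VENC"):
            df.make_helical_phantom(spec)


class TestDissectionPhantom:
    def test_degenerate_full_tl_starves_false_lumen(self):
        spec = df.PhantomSpec(radius_mm=12.0, length_mm=60.0,
                              waveform="systolic-pulse")
        _, mask, gt = df.make_dissection_phantom(spec, 1.0, 0.0,
                                                 pocket_fraction=0.0)
        assert gt.stasis_pct_noiseless["false_lumen"] == 100.0
        assert gt.net_ml["false_lumen"] == 0.0

    def test_forward_only_split(self):
        spec = df.PhantomSpec(radius_mm=12.0, length_mm=60.0,
                              waveform="systolic-pulse")
        _, _, gt = df.make_dissection_phantom(spec, 0.6, 0.0,
                                              total_volume_ml=70.0,
                                              pocket_fraction=0.0)
        assert gt.forward_ml["false_lumen"] == pytest.approx(0.4 * 70.0)
        assert gt.reverse_ml["false_lumen"] == 0.0

    def test_half_reverse_cancels_fl_net(self):
        spec = df.PhantomSpec(radius_mm=12.0, length_mm=60.0,
                              waveform="systolic-pulse")
        _, _, gt = df.make_dissection_phantom(spec, 0.6, 0.5,
                                              pocket_fraction=0.0)
        assert gt.net_ml["false_lumen"] == pytest.approx(0.0, abs=1e-9)

    def test_fraction_bounds_enforced(self):
        spec = df.PhantomSpec(radius_mm=12.0, length_mm=60.0)
        with pytest.raises(df.ParameterError):
            df.make_dissection_phantom(spec, 0.0, 0.3)
        with pytest.raises(df.ParameterError):
            df.make_dissection_phantom(spec, 0.6, 1.5)

    def test_net_equals_forward_plus_reverse(self, dissection):
        _, _, gt = dissection
        for region in gt.net_ml:
            assert gt.net_ml[region] == pytest.approx(
                gt.forward_ml[region] + gt.reverse_ml[region])

    def test_septum_separates_lumens_and_carries_no_flow(self, dissection):
        fld, mask, gt = dissection
        tl = mask.region(LABELS["true_lumen"])
        fl = mask.region(LABELS["false_lumen"])
        assert not np.any(tl & fl)
        # septum column between the halves is background
        assert mask.counts()["background"] > 0

    def test_branch_carries_requested_fraction(self):
        spec = df.PhantomSpec(radius_mm=12.0, length_mm=80.0,
                              waveform="systolic-pulse")
        _, _, gt = df.make_dissection_phantom(spec, 0.6, 0.0,
                                              branch_fraction=0.15,
                                              pocket_fraction=0.0)
        assert gt.net_ml["branch_1"] == pytest.approx(
            0.15 * gt.net_ml["ascending"])


class TestStentNoise:
    def test_zero_amplitude_is_identity(self, tube):
        fld, mask, _ = tube
        idx = np.argwhere(mask.lumen())[:10]
        out = df.inject_stent_noise(fld, idx, 0.0, seed=0)
        assert np.array_equal(out.values, fld.values)

    def test_exactly_the_region_voxels_differ(self, tube, rng):
        fld, mask, _ = tube
        lum = np.argwhere(mask.lumen())
        idx = lum[rng.choice(len(lum), 50, replace=False)]
        out = df.inject_stent_noise(fld, idx, 2.0, seed=1)
        diff = np.any(out.values != fld.values, axis=(3, 4))
        assert int(diff.sum()) == 50
        want = set(map(tuple, idx))
        got = set(map(tuple, np.argwhere(diff)))
        assert got == want

    def test_corrupted_region_has_higher_gradient_statistic(self, tube, rng):
        from dissectflow.preprocess import temporal_summed_gradient
        fld, mask, _ = tube
        lum = np.argwhere(mask.lumen())
        idx = lum[rng.choice(len(lum), 50, replace=False)]
        out = df.inject_stent_noise(fld, idx, 2.0, seed=1)
        g = temporal_summed_gradient(out)
        inj = np.zeros(mask.grid_shape, bool)
        inj[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        clean_lumen = mask.lumen() & ~inj
        assert g[inj].min() > g[clean_lumen].mean()

    def test_empty_region_warns_and_copies(self, tube):
        fld, _, _ = tube
        with pytest.warns(UserWarning, match="empty"):
            out = df.inject_stent_noise(fld, np.empty((0, 3), int), 1.0)
        assert np.array_equal(out.values, fld.values)

    def test_records_region_on_ground_truth(self, tube):
        fld, mask, _ = tube
        gt = df.GroundTruth()
        idx = np.argwhere(mask.lumen())[:5]
        df.inject_stent_noise(fld, idx, 1.0, seed=0, ground_truth=gt)
        assert np.array_equal(gt.stent_voxels, idx)


class TestExpectedStasis:
    def test_noise_free_is_indicator(self):
        speeds = np.array([[0.05, 0.2, 0.05, 0.05]])
        assert expected_stasis_pct(speeds, 0.0) == 75.0

    def test_zero_speed_under_noise_matches_chi3(self):
        # P(||N(0, sigma^2 I_3)|| < thr) for sigma=0.05, thr=0.1
        from scipy import stats
        got = expected_stasis_pct(np.zeros((1, 1)), 0.05, 0.1)
        want = 100 * stats.chi2.cdf((0.1 / 0.05) ** 2, df=3)
        assert got == pytest.approx(want)

    def test_fast_flow_never_stasis(self):
        assert expected_stasis_pct(np.full((5, 5), 1.0), 0.05) < 1e-6
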