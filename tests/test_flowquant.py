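"""Flux integration, parametric maps, normalization, branch planes."""

import numpy as np
import pytest

import dissectflow as df
from dissectflow.fields import LABELS, VelocityField4D
from dissectflow.flowquant import FlowSummary, band_sums
from dissectflow.phantom import waveform_function


class TestClassifyDirection:
    def test_aligned_velocity_is_forward(self):
        t = np.array([0.0, 0.0, 1.0])
        assert df.classify_direction(t * 0.8, t) == pytest.approx(0.8)

    def test_in_plane_swirl_contributes_nothing(self):
        assert df.classify_direction([0.5, -0.3, 0.0],
                                     [0.0, 0.0, 1.0]) == pytest.approx(0.0)

    def test_opposed_velocity_is_reverse(self):
        t = np.array([0.0, 0.0, 1.0])
        assert df.classify_direction(-t * 0.3, t) == pytest.approx(-0.3)

    def test_non_unit_tangent_rejected(self):
        with pytest.raises(df.ParameterError):
            df.classify_direction([1.0, 0, 0], [0, 0, 2.0])


class TestSectionFlow:
    def test_steady_tube_matches_analytic_flux(self, tube, tube_sections):
        fld, _, gt = tube
        mid = tube_sections[len(tube_sections) // 2]
        fc = df.section_flow(fld, mid)
        assert fc.net_mls[0] == pytest.approx(157.08, rel=0.02)
        assert np.all(fc.reverse_mls == 0.0)

    def test_sign_flip_swaps_forward_reverse(self, tube, tube_sections):
        fld, _, _ = tube
        flipped = fld.copy()
        flipped.values *= -1.0
        sec = tube_sections[40]
        a = df.section_flow(fld, sec)
        b = df.section_flow(flipped, sec)
        assert np.allclose(b.net_mls, -a.net_mls)
        assert np.allclose(b.reverse_mls, -a.forward_mls)
        assert np.allclose(b.forward_mls, -a.reverse_mls)

    def test_pulsatile_volumes_match_waveform_quadrature(self):
        spec = df.PhantomSpec(waveform="sinusoid", n_phases=20,
                              length_mm=60.0)
        fld, mask, _ = df.make_tube_phantom(spec)
        skel = df.extract_skeleton(mask)
        cl = df.resample(df.order_and_prune(skel, [0, 0, 0], mask.affine), 1.0)
        sec = df.place_cross_sections(cl, mask)[len(cl) // 2]
        fc = df.section_flow(fld, sec)
        # independent quadrature of the waveform at the phantom's phase
        # centers times the steady Poiseuille flow
        w = waveform_function("sinusoid")((np.arange(20) + 0.5) / 20)
        q0 = 1.0 * np.pi * 10.0 ** 2 / 2
        dt = 0.05
        assert fc.forward_ml == pytest.approx(
            float(np.sum(np.maximum(w, 0)) * dt * q0), rel=0.03)
        assert fc.reverse_ml == pytest.approx(
            float(np.sum(np.minimum(w, 0)) * dt * q0), rel=0.03)

    def test_net_is_forward_plus_reverse_machine_precision(
            self, dissection, dissection_sections):
        fld, _, _ = dissection
        for sec in dissection_sections[::25]:
            fc = df.section_flow(fld, sec)
            assert np.allclose(fc.net_mls,
                               fc.forward_mls + fc.reverse_mls,
                               rtol=0, atol=1e-12)

    def test_conservation_along_straight_tube(self, tube, tube_sections):
        fld, _, _ = tube
        vols = [df.section_flow(fld, s).net_ml
                for s in tube_sections[10:-10]]
        vols = np.array(vols)
        assert (vols.max() - vols.min()) / vols.mean() < 0.02

    def test_empty_section_flagged(self, tube):
        fld, mask, _ = tube
        from dissectflow.centerline import Centerline
        pts = np.column_stack([np.full(3, 90.0), np.full(3, 90.0),
                               np.arange(3.0)])
        sec = df.place_cross_sections(Centerline(pts), mask)[1]
        fc = df.section_flow(fld, sec)
        assert fc.is_empty
        assert fc.net_ml == 0.0


class TestMaps:
    def test_uniform_forward_field_has_zero_rf(self, tube, tube_centerline):
        fld, mask, _ = tube
        ff, rf = df.ff_rf_maps(fld, mask, tube_centerline)
        lum = mask.lumen()
        assert np.all(rf.values[lum] == 0.0)
        assert np.all(ff.values[lum] >= 0.0)

    def test_band_sums_reconcile_with_section_volumes(
            self, tube, tube_centerline, tube_sections):
        fld, mask, _ = tube
        ff, _ = df.ff_rf_maps(fld, mask, tube_centerline)
        bands = band_sums(ff, mask, tube_centerline)
        for i in range(20, len(tube_sections) - 20, 15):
            fwd = df.section_flow(fld, tube_sections[i]).forward_ml
            assert bands[i] == pytest.approx(fwd, rel=0.05)

    def test_time_reversal_sign_flip_swaps_maps(self, dissection,
                                                dissection_centerline):
        fld, mask, _ = dissection
        rev = fld.copy()
        rev.values = -fld.values[..., ::-1]
        ff1, rf1 = df.ff_rf_maps(fld, mask, dissection_centerline)
        ff2, rf2 = df.ff_rf_maps(rev, mask, dissection_centerline)
        lum = mask.lumen()
        assert np.allclose(ff2.values[lum], -rf1.values[lum], atol=1e-9)
        assert np.allclose(rf2.values[lum], -ff1.values[lum], atol=1e-9)

    def test_stasis_exact_counting(self):
        # 18 of 20 phases below 0.1 m/s -> exactly 90%
        vals = np.zeros((3, 3, 3, 3, 20))
        vals[..., 2, :18] = 0.05
        vals[..., 2, 18:] = 0.5
        fld = VelocityField4D(vals, np.eye(4), 50.0)
        mask = df.LumenMask(np.ones((3, 3, 3), np.int16), np.eye(4))
        sm = df.stasis_map(fld, mask)
        assert np.all(sm.values == 90.0)

    def test_stasis_zero_and_fast_fields(self):
        mask = df.LumenMask(np.ones((2, 2, 2), np.int16), np.eye(4))
        zero = VelocityField4D(np.zeros((2, 2, 2, 3, 20)), np.eye(4), 50.0)
        assert np.all(df.stasis_map(zero, mask).values == 100.0)
        fast = VelocityField4D(np.full((2, 2, 2, 3, 20), 0.2), np.eye(4), 50.0)
        assert np.all(df.stasis_map(fast, mask).values == 0.0)

    def test_stasis_threshold_monotonicity(self, dissection):
        fld, mask, _ = dissection
        lo = df.stasis_map(fld, mask, 0.05).values
        hi = df.stasis_map(fld, mask, 0.1).values
        lum = mask.lumen()
        assert np.all(hi[lum] >= lo[lum])


class TestSegmentAverage:
    def _cl(self, n=50):
        from dissectflow.centerline import Centerline
        pts = np.column_stack([np.zeros(n), np.zeros(n), np.arange(float(n))])
        cl = Centerline(pts)
        cl.landmarks = {"left_subclavian": 10, "celiac_trunk": 40}
        return cl

    def test_constant_values(self):
        cl = self._cl()
        got = df.segment_average(np.full(50, 3.7), cl, "left_subclavian",
                                 "celiac_trunk")
        assert got == pytest.approx(3.7)

    def test_single_section_range(self):
        cl = self._cl()
        cl.landmarks["celiac_trunk"] = 10
        vals = np.arange(50.0)
        assert df.segment_average(vals, cl, "left_subclavian",
                                  "celiac_trunk") == 10.0

    def test_linear_ramp_gives_midpoint(self):
        cl = self._cl()
        vals = np.linspace(0, 49, 50)
        got = df.segment_average(vals, cl, "left_subclavian", "celiac_trunk")
        assert got == pytest.approx((10 + 40) / 2)

    def test_missing_landmark_rejected(self):
        cl = self._cl()
        with pytest.raises(df.DataError):
            df.segment_average(np.zeros(50), cl, "left_subclavian", "sinus")


class TestNormalizeAndCompare:
    def _summary(self, tl_net, fl_net=1.0, asc_net=4.0):
        return FlowSummary(regions={
            "ascending": {"net_ml": asc_net, "forward_ml": asc_net,
                          "reverse_ml": 0.0},
            "true_lumen": {"net_ml": tl_net, "forward_ml": tl_net,
                           "reverse_ml": 0.0},
            "false_lumen": {"net_ml": fl_net, "forward_ml": fl_net,
                            "reverse_ml": 0.0},
        })

    def test_normalization_to_ascending(self):
        s = self._summary(tl_net=2.0, asc_net=4.0)
        assert s.normalized()["true_lumen"]["net_norm_pct"] == 50.0
        assert s.normalized()["ascending"]["net_norm_pct"] == 100.0

    def test_identical_summaries_give_zero_change(self):
        s = self._summary(2.0)
        table = df.normalize_and_compare(s, s)
        assert np.allclose(table["relative_change_pct"], 0.0)

    def test_relative_change_formula(self):
        # normalized net 4.4% -> 0.9% gives a -79.5% relative change
        pre = self._summary(tl_net=2.0, fl_net=4.4, asc_net=100.0)
        post = self._summary(tl_net=2.0, fl_net=0.9, asc_net=100.0)
        table = df.normalize_and_compare(pre, post)
        row = table[(table.region == "false_lumen")
                    & (table.quantity == "net_norm_pct")]
        assert row["relative_change_pct"].iloc[0] == pytest.approx(
            100 * (0.9 - 4.4) / 4.4, abs=0.05)

    def test_zero_pre_reported_missing_not_infinite(self):
        pre = self._summary(tl_net=0.0)
        post = self._summary(tl_net=1.0)
        table = df.normalize_and_compare(pre, post)
        row = table[(table.region == "true_lumen")
                    & (table.quantity == "net_norm_pct")]
        assert np.isnan(row["relative_change_pct"].iloc[0])

    def test_zero_reference_rejected(self):
        s = self._summary(2.0, asc_net=0.0)
        with pytest.raises(df.DataError):
            s.normalized()


@pytest.fixture(scope="module")
def branched():
    spec = df.PhantomSpec(radius_mm=12.0, length_mm=80.0,
                          waveform="systolic-pulse")
    return df.make_dissection_phantom(spec, 0.6, 0.0, branch_fraction=0.15,
                                      pocket_fraction=0.0)


class TestBranchPlaneFlow:

    def test_branch_carries_fifteen_percent_of_inflow(self, branched):
        fld, mask, gt = branched
        z_b = gt.meta["z_ascending_end_mm"] + 10.0
        fc = df.branch_plane_flow(fld, mask, [20.0, 0.0, z_b],
                                  [1.0, 0.0, 0.0], radius_mm=8.0,
                                  label=LABELS["branch_1"])
        assert fc.net_ml == pytest.approx(0.15 * gt.net_ml["ascending"],
                                          rel=0.02)

    def test_reversed_normal_negates_flow(self, branched):
        fld, mask, gt = branched
        z_b = gt.meta["z_ascending_end_mm"] + 10.0
        a = df.branch_plane_flow(fld, mask, [20.0, 0.0, z_b], [1, 0, 0],
                                 radius_mm=8.0, label=LABELS["branch_1"])
        b = df.branch_plane_flow(fld, mask, [20.0, 0.0, z_b], [-1, 0, 0],
                                 radius_mm=8.0, label=LABELS["branch_1"])
        assert b.net_ml == pytest.approx(-a.net_ml)

    def test_plane_missing_branch_is_empty(self, branched):
        fld, mask, _ = branched
        fc = df.branch_plane_flow(fld, mask, [0.0, 0.0, 5.0], [1, 0, 0],
                                  radius_mm=5.0, label=LABELS["branch_1"])
        assert fc.is_empty
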