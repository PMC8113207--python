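import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectquant import (
    apical_sparing_dpd,
    apical_sparing_echo,
    decay_correct,
    quantify_study,
    region_metrics,
    segment_isocontour,
    suv,
    suv_factor,
)
from spectquant.phantom import PhantomSpec, make_phantom
from spectquant.quantify import UptakeMetrics

from conftest import make_meta, make_volume
from oracles import region_metrics_tripleloop


class TestDecayCorrect:
    def test_zero_delay_is_identity(self):
        meta = make_meta(delay_h=0.0)
        assert decay_correct(7.3, meta) == 7.3

    def test_one_half_life_doubles(self):
        meta = make_meta(delay_h=6.0067, half_life_h=6.0067)
        assert decay_correct(5.0, meta) == pytest.approx(10.0, rel=1e-12)

    def test_three_hour_protocol_value(self):
        meta = make_meta(delay_h=3.0, half_life_h=6.0067)
        # independent closed form: 10 * exp(ln2 * 3 / 6.0067)
        expected = 10.0 * math.exp(math.log(2.0) * 3.0 / 6.0067)
        assert decay_correct(10.0, meta) == pytest.approx(expected, rel=1e-12)
        assert decay_correct(10.0, meta) == pytest.approx(14.136669677, abs=1e-6)


class TestSuv:
    def test_dose_equals_weight_is_identity(self):
        meta = make_meta(dose=70.0, weight=70.0)
        assert suv(123.4, meta) == pytest.approx(123.4, rel=1e-12)

    def test_protocol_values(self):
        meta = make_meta(dose=740.0, weight=74.6)
        assert suv(500.0, meta) == pytest.approx(500.0 * 74.6 / 740.0, rel=1e-12)
        assert suv(500.0, meta) == pytest.approx(50.405405, abs=1e-5)

    def test_zero_concentration(self):
        assert suv(0.0, make_meta()) == 0.0


class TestSegmentIsocontour:
    def test_uniform_voi_fully_retained(self):
        vol = make_volume(np.full((3, 3, 3), 7.0))
        voi = np.ones((3, 3, 3), dtype=bool)
        seg = segment_isocontour(vol, voi, 0.42)
        assert np.array_equal(seg, voi)

    def test_inclusive_threshold_rule(self):
        values = np.zeros((1, 1, 4))
        values[0, 0] = [100.0, 50.0, 42.0, 41.0]
        vol = make_volume(values)
        voi = np.ones((1, 1, 4), dtype=bool)
        seg = segment_isocontour(vol, voi, 0.42)
        assert seg[0, 0].tolist() == [True, True, True, False]

    def test_single_voxel_voi(self):
        vol = make_volume(np.arange(8.0).reshape(2, 2, 2))
        voi = np.zeros((2, 2, 2), dtype=bool)
        voi[1, 1, 1] = True
        seg = segment_isocontour(vol, voi, 0.42)
        assert seg.sum() == 1 and seg[1, 1, 1]

    def test_all_zero_voi_degenerate_warns(self):
        vol = make_volume(np.zeros((2, 2, 2)))
        voi = np.ones((2, 2, 2), dtype=bool)
        with pytest.warns(UserWarning, match="degenerate"):
            seg = segment_isocontour(vol, voi, 0.42)
        assert np.array_equal(seg, voi)

    def test_empty_voi_rejected(self):
        vol = make_volume(np.ones((2, 2, 2)))
        with pytest.raises(ValueError, match="empty"):
            segment_isocontour(vol, np.zeros((2, 2, 2), dtype=bool))

    @pytest.mark.parametrize("fraction", [0.0, -0.1, 1.5])
    def test_fraction_out_of_range_rejected(self, fraction):
        vol = make_volume(np.ones((2, 2, 2)))
        with pytest.raises(ValueError, match="fraction"):
            segment_isocontour(vol, np.ones((2, 2, 2), dtype=bool), fraction)


class TestRegionMetrics:
    def test_hand_arithmetic_row(self, meta_identity):
        # thresholded SUVs {100, 60, 50}, voxel 0.5 mL
        values = np.zeros((1, 1, 4))
        values[0, 0] = [100.0, 60.0, 50.0, 1.0]
        vol = make_volume(values, spacing=(10.0, 10.0, 5.0))  # 0.5 mL voxels
        voi = np.ones((1, 1, 4), dtype=bool)
        m = region_metrics(vol, voi, meta_identity, fraction=0.42)
        assert m.dpd_mean == pytest.approx(70.0)
        assert m.dpd_max == pytest.approx(100.0)
        assert m.v42_ml == pytest.approx(1.5)
        assert m.dpd_load == pytest.approx(105.0)
        assert m.n_voxels_anatomical == 4
        assert m.n_voxels_thresholded == 3

    def test_fraction_one_keeps_argmax_only(self, meta_identity, rng):
        vol = make_volume(rng.random((4, 4, 4)))
        voi = np.ones((4, 4, 4), dtype=bool)
        m = region_metrics(vol, voi, meta_identity, fraction=1.0)
        assert m.dpd_mean == pytest.approx(m.dpd_max, rel=1e-12)
        assert m.n_voxels_thresholded >= 1

    def test_merged_max_is_member_max(self, meta_identity):
        vol, masks, _ = make_phantom(
            PhantomSpec(shape=(64, 64, 64), psf_fwhm_mm=0.0)
        )
        members = ["LV_LATERAL", "IVS", "APEX"]
        member_max = max(
            region_metrics(vol, masks.mask(n), meta_identity).dpd_max for n in members
        )
        lv = np.zeros(vol.shape, dtype=bool)
        for n in members:
            lv |= masks.mask(n)
        assert region_metrics(vol, lv, meta_identity).dpd_max == pytest.approx(
            member_max, rel=1e-12
        )

    def test_invariant_mean_above_fraction_of_max(self, meta_3h, rng):
        for _ in range(20):
            vol = make_volume(rng.random((5, 5, 5)) * 100)
            voi = rng.random((5, 5, 5)) < 0.7
            if not voi.any():
                continue
            m = region_metrics(vol, voi, meta_3h, fraction=0.42)
            assert m.dpd_mean >= 0.42 * m.dpd_max - 1e-9
            assert m.dpd_max >= m.dpd_mean

    def test_oracle_equivalence_small_volumes(self, meta_3h, rng):
        factor = suv_factor(meta_3h)
        for _ in range(25):
            shape = tuple(rng.integers(2, 7, size=3))
            vol = make_volume(rng.random(shape) * 50)
            voi = rng.random(shape) < 0.6
            if not voi.any():
                continue
            m = region_metrics(vol, voi, meta_3h, fraction=0.42)
            ref = region_metrics_tripleloop(
                vol.values, voi, vol.spacing_mm, factor, 0.42
            )
            assert m.dpd_mean == ref[0]
            assert m.dpd_max == ref[1]
            assert m.v42_ml == ref[2]
            assert m.dpd_load == ref[3]
            assert (m.n_voxels_anatomical, m.n_voxels_thresholded) == ref[4:]


class TestProperties:
    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_equivariance(self, c):
        rng = np.random.default_rng(7)
        base = rng.random((4, 4, 4)) * 10 + 0.1
        voi = np.ones((4, 4, 4), dtype=bool)
        meta = make_meta()
        m1 = region_metrics(make_volume(base), voi, meta)
        m2 = region_metrics(make_volume(base * c), voi, meta)
        assert m2.dpd_mean == pytest.approx(c * m1.dpd_mean, rel=1e-9)
        assert m2.dpd_max == pytest.approx(c * m1.dpd_max, rel=1e-9)
        assert m2.dpd_load == pytest.approx(c * m1.dpd_load, rel=1e-9)
        assert m2.v42_ml == m1.v42_ml
        assert m2.n_voxels_thresholded == m1.n_voxels_thresholded

    def test_threshold_monotonicity(self, meta_3h, rng):
        vol = make_volume(rng.random((6, 6, 6)) * 80)
        voi = np.ones((6, 6, 6), dtype=bool)
        fractions = (0.2, 0.42, 0.6, 0.8, 1.0)
        rows = [region_metrics(vol, voi, meta_3h, f) for f in fractions]
        for lo, hi in zip(rows, rows[1:]):
            assert hi.v42_ml <= lo.v42_ml
            assert hi.dpd_mean >= lo.dpd_mean - 1e-12
            assert hi.dpd_max == pytest.approx(lo.dpd_max, rel=1e-12)


class TestSparing:
    def test_dpd_ratio_cohort_means(self):
        res = apical_sparing_dpd(36.5, 54.6, 43.4)
        assert res.ratio == pytest.approx(36.5 / 49.0, rel=1e-12)
        assert res.sparing_flag is None

    def test_dpd_ratio_trivia(self):
        assert apical_sparing_dpd(5.0, 5.0, 5.0).ratio == pytest.approx(1.0)
        assert apical_sparing_dpd(0.0, 3.0, 3.0).ratio == 0.0
        with pytest.raises(ValueError):
            apical_sparing_dpd(1.0, 0.0, 0.0)

    def test_echo_ratio_cutoff_strict(self):
        res = apical_sparing_echo(-24.0, -10.0, -14.0)
        assert res.ratio == pytest.approx(1.0)
        assert res.sparing_flag is False  # strict > 1

    def test_echo_ratio_sparing(self):
        res = apical_sparing_echo(-30.0, -10.0, -10.0)
        assert res.ratio == pytest.approx(1.5)
        assert res.sparing_flag is True

    def test_echo_ratio_equal_segments(self):
        res = apical_sparing_echo(-12.0, -12.0, -12.0)
        assert res.ratio == pytest.approx(0.5)
        assert res.sparing_flag is False

    def test_echo_zero_denominator(self):
        with pytest.raises(ValueError):
            apical_sparing_echo(-24.0, 5.0, -5.0)

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=20, deadline=None)
    def test_ratios_scale_invariant(self, c):
        a = apical_sparing_dpd(36.5, 54.6, 43.4).ratio
        b = apical_sparing_dpd(36.5 * c, 54.6 * c, 43.4 * c).ratio
        assert b == pytest.approx(a, rel=1e-9)
        a = apical_sparing_echo(-24.0, -10.0, -14.0).ratio
        b = apical_sparing_echo(-24.0 * c, -10.0 * c, -14.0 * c).ratio
        assert b == pytest.approx(a, rel=1e-9)


class TestUptakeMetricsInvariants:
    def test_counts_checked(self):
        with pytest.raises(ValueError):
            UptakeMetrics("X", 1.0, 2.0, 1.0, 1.0, 3, 4)

    def test_ordering_checked(self):
        with pytest.raises(ValueError):
            UptakeMetrics("X", 5.0, 2.0, 1.0, 5.0, 4, 3)


class TestQuantifyStudy:
    def test_table_shape_and_consistency(self, meta_3h):
        vol, masks, _ = make_phantom(PhantomSpec(shape=(64, 64, 64)))
        table = quantify_study(vol, masks, meta_3h)
        assert list(table["region"]) == [
            "LV_LATERAL", "IVS", "APEX", "RV_FREE_WALL", "LV", "VENTRICLES",
        ]
        assert (table["n_voxels_thresholded"] <= table["n_voxels_anatomical"]).all()
        np.testing.assert_allclose(
            table["dpd_load"], table["dpd_mean"] * table["v42_ml"], rtol=1e-12
        )
        by = table.set_index("region")
        # merged-region maxima dominate members; ventricles max >= LV max
        assert by.loc["VENTRICLES", "dpd_max"] >= by.loc["LV", "dpd_max"] - 1e-12
        # sternum margin trims the anatomical RV VOI
        assert by.loc["RV_FREE_WALL", "n_voxels_anatomical"] < int(
            masks.mask("RV_FREE_WALL").sum()
        )
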