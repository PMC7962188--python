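"""Error statistics, Fisher-Z correlation averaging, BHS/AAMI compliance,
Bland-Altman pairs, per-range accuracy, histograms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wavebp.bp_extract import BPWindowEstimate
from wavebp.errors import ParameterError
from wavebp.evaluate import (aami_check, average_correlation, bhs_grade,
                             bland_altman, error_histogram, error_stats,
                             per_range_accuracy)


class TestErrorStats:
    def test_identical_vectors(self):
        s = error_stats([120, 130, 110], [120, 130, 110])
        assert (s.mae, s.std, s.rmse) == (0.0, 0.0, 0.0)
        assert s.r == pytest.approx(1.0)

    def test_constant_offset(self):
        s = error_stats(np.array([100, 110, 120]) + 2, [100, 110, 120])
        assert s.mae == pytest.approx(2.0)
        assert s.std == pytest.approx(0.0)
        assert s.rmse == pytest.approx(2.0)
        assert s.r == pytest.approx(1.0)

    def test_hand_computation(self):
        pred, ref = [120, 130, 110], [118, 135, 112]
        s = error_stats(pred, ref)
        errs = np.array([2.0, -5.0, -2.0])
        assert s.mae == pytest.approx(np.abs(errs).mean())
        assert s.rmse == pytest.approx(np.sqrt((errs ** 2).mean()))
        assert s.std == pytest.approx(np.abs(errs).std(ddof=1))

    def test_constant_vector_r_flagged_nan(self):
        s = error_stats([100, 100, 100], [99, 101, 100])
        assert math.isnan(s.r)

    def test_invariant_rmse_bounds_mean_error(self, rng):
        pred = rng.normal(100, 10, 50)
        ref = rng.normal(100, 10, 50)
        s = error_stats(pred, ref)
        assert s.rmse >= abs(np.mean(pred - ref)) - 1e-12


class TestAverageCorrelation:
    def test_constant_inputs(self):
        assert average_correlation([0.5, 0.5, 0.5]).avg_r == pytest.approx(0.5)
        assert average_correlation([0.0, 0.0]).avg_r == pytest.approx(0.0)

    def test_two_value_closed_form(self):
        # tanh((atanh 0.9 + atanh 0.99) / 2), computed independently
        assert average_correlation([0.9, 0.99]).avg_r == pytest.approx(
            0.9679947954716546, abs=1e-12)

    def test_percentiles_on_raw_values(self):
        r = [0.1, 0.2, 0.3, 0.4]
        s = average_correlation(r)
        assert s.min_r == 0.1 and s.max_r == 0.4
        assert s.p25_r == pytest.approx(np.percentile(r, 25))
        assert s.p75_r == pytest.approx(np.percentile(r, 75))

    def test_unit_correlation_clipped_and_flagged(self):
        s = average_correlation([1.0, 0.5])
        assert s.clipped == 1
        assert np.isfinite(s.avg_r)

    @given(st.lists(st.floats(0.01, 0.99), min_size=2, max_size=30))
    @settings(max_examples=60, deadline=None)
    def test_fisher_average_dominates_arithmetic_for_positive_r(self, rs):
        # atanh is convex on (0, 1), so the transformed average is >= the
        # arithmetic mean
        s = average_correlation(rs)
        assert s.avg_r >= np.mean(rs) - 1e-12

    def test_summary_ordering_invariant(self, rng):
        r = rng.uniform(-0.9, 0.99, 40)
        s = average_correlation(r)
        assert s.min_r <= s.p25_r <= s.p75_r <= s.max_r


class TestBHSGrade:
    def test_all_zero_errors_grade_a(self):
        res = bhs_grade(np.zeros(50))
        assert (res.cum5, res.cum10, res.cum15) == (100.0, 100.0, 100.0)
        assert res.grade == "A"

    def test_all_errors_12mmhg_grade_d(self):
        res = bhs_grade(np.full(20, 12.0))
        assert (res.cum5, res.cum10, res.cum15) == (0.0, 0.0, 100.0)
        assert res.grade == "D"

    def test_six_value_hand_count(self):
        res = bhs_grade([3, 3, 3, 7, 14, 20])
        assert res.cum5 == pytest.approx(50.0)
        assert res.cum10 == pytest.approx(100 * 4 / 6)
        assert res.cum15 == pytest.approx(100 * 5 / 6)
        assert res.grade == "D"  # fails C's 85% at <= 15 mmHg

    def test_thresholds_inclusive(self):
        res = bhs_grade([5.0, 10.0, 15.0])
        assert (res.cum5, res.cum10, res.cum15) == pytest.approx(
            (100 / 3, 200 / 3, 100.0))

    def test_grade_b_case(self):
        errs = np.concatenate([np.full(55, 3.0), np.full(25, 8.0),
                               np.full(12, 13.0), np.full(8, 20.0)])
        res = bhs_grade(errs)
        assert res.grade == "B"

    def test_negative_errors_rejected(self):
        with pytest.raises(ParameterError):
            bhs_grade([-1.0, 2.0])

    @given(st.lists(st.floats(0, 40), min_size=1, max_size=60))
    @settings(max_examples=60, deadline=None)
    def test_appending_zero_error_never_worsens_grade(self, errs):
        order = "DCBA"
        before = order.index(bhs_grade(errs).grade)
        after = order.index(bhs_grade(errs + [0.0]).grade)
        assert after >= before


class TestAAMICheck:
    def test_constant_3mmhg_error_passes(self):
        res = aami_check(np.array([103.0] * 10), np.array([100.0] * 10), 100)
        assert res.mean_stat == pytest.approx(3.0)
        assert res.std_stat == pytest.approx(0.0)
        assert res.passed

    def test_alternating_12mmhg_fails_on_std(self):
        ref = np.full(40, 100.0)
        pred = ref + np.tile([12.0, -12.0], 20)
        res = aami_check(pred, ref, 100)
        assert res.mean_stat == pytest.approx(0.0)
        assert res.std_stat == pytest.approx(12.0, rel=0.02)
        assert not res.passed

    def test_mean_6_fails_on_mean_bound(self, rng):
        ref = rng.normal(100, 5, 200)
        pred = ref + 6.0 + rng.normal(0, 4, 200)
        res = aami_check(pred, ref, 90)
        assert abs(res.mean_stat) > 5.0
        assert not res.passed

    def test_subject_count_reported(self):
        res = aami_check([100.0, 101.0], [100.0, 100.0], 86)
        assert res.enough_subjects
        assert not aami_check([100.0, 101.0], [100.0, 100.0],
                              85).enough_subjects

    def test_absolute_statistic_switch(self):
        ref = np.full(10, 100.0)
        pred = ref + np.tile([4.0, -4.0], 5)
        assert aami_check(pred, ref, 10).mean_stat == pytest.approx(0.0)
        assert aami_check(pred, ref, 10,
                          statistic="absolute").mean_stat == pytest.approx(4.0)


class TestBlandAltman:
    def test_identity_gives_zero_bias(self):
        pts, bias, loa = bland_altman([100, 120], [100, 120])
        assert bias == 0.0
        np.testing.assert_array_equal(pts[:, 1], [0.0, 0.0])

    def test_large_difference_clipped_at_30(self):
        pts, bias, _ = bland_altman([135.0], [100.0])
        assert pts[0, 1] == 30.0
        assert bias == pytest.approx(35.0)  # bias itself is unclipped

    def test_simple_pair(self):
        pts, _, _ = bland_altman([110.0], [100.0])
        np.testing.assert_allclose(pts[0], [105.0, 10.0])

    def test_bias_equals_mean_difference(self, rng):
        pred = rng.normal(120, 10, 100)
        ref = rng.normal(118, 10, 100)
        _, bias, loa = bland_altman(pred, ref)
        assert bias == pytest.approx(pred.mean() - ref.mean())
        sd = (pred - ref).std(ddof=1)
        assert loa[1] - loa[0] == pytest.approx(2 * 1.96 * sd)


def est(sbp, dbp, map_=None, wid=""):
    return BPWindowEstimate(sbp=sbp, dbp=dbp,
                            map=map_ if map_ is not None else (sbp + 2 * dbp) / 3,
                            n_peaks=2, n_valleys=2, window_id=wid)


class TestPerRangeAccuracy:
    def test_exact_predictions_give_diagonal(self):
        pairs = [(est(110, 70), est(110, 70)),
                 (est(130, 85), est(130, 85)),
                 (est(150, 95), est(150, 95)),
                 (est(170, 105), est(170, 105))]
        out = per_range_accuracy(pairs)
        conf = out["confusion"]
        assert conf.sum() == 4
        assert np.trace(conf) == 4
        for rng_label in out["labels"]:
            assert out["within_fraction"][rng_label]["sbp"] in (1.0,)

    def test_within_10_fraction_counts(self):
        pairs = [(est(110, 70), est(110, 70)) for _ in range(3)]
        pairs.append((est(112, 70), est(124, 70)))  # SBP error 12
        out = per_range_accuracy(pairs)
        assert out["within_fraction"]["normal"]["sbp"] == pytest.approx(0.75)
        assert out["within_fraction"]["normal"]["dbp"] == pytest.approx(1.0)

    def test_cross_range_confusion_cell(self):
        pairs = [(est(145, 85), est(138, 85))]  # stage-1 -> pre-hypertension
        out = per_range_accuracy(pairs)
        conf = out["confusion"]
        i = out["labels"].index("stage-1")
        j = out["labels"].index("pre-hypertension")
        assert conf[i, j] == 1

    def test_empty_group_is_nan_not_error(self):
        out = per_range_accuracy([(est(110, 70), est(110, 70))])
        assert math.isnan(out["within_fraction"]["stage-2"]["sbp"])


class TestErrorHistogram:
    def test_three_unit_errors(self):
        edges, counts = error_histogram([-1.0, 0.0, 1.0], bin_width=1.0)
        assert counts.sum() == 3
        assert (counts > 0).sum() == 3
        # bins are centered on zero
        centers = (edges[:-1] + edges[1:]) / 2
        assert 0.0 in centers

    def test_counts_conserved(self, rng):
        errs = rng.normal(0, 5, 500)
        _, counts = error_histogram(errs, bin_width=2.0)
        assert counts.sum() == 500

    def test_mirrored_input_symmetric_counts(self, rng):
        half = rng.uniform(0.1, 9.9, 100)
        errs = np.concatenate([half, -half])
        _, counts = error_histogram(errs, bin_width=1.0)
        np.testing.assert_array_equal(counts, counts[::-1])

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ParameterError):
            error_histogram([], 1.0)
        with pytest.raises(ParameterError):
            error_histogram([1.0], 0.0)
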