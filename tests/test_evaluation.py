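"""Sensitivity/specificity tables, AUC, threshold selection, PPV,
recurrence-risk splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sibscore as sb
from sibscore.evaluation import ThresholdSelectionError, metrics_at
from sibscore.reference import load_reference_threshold_table


class TestSensSpecTable:
    def test_min_threshold_has_full_sensitivity(self):
        table = sb.sens_spec_table([5, 6, 9], [4, 7])
        assert table[0].threshold == 4
        assert table[0].sensitivity == 1.0

    def test_above_max_classifies_nothing_positive(self):
        m = metrics_at([5, 6, 9], [4, 7], threshold=10)
        assert m.sensitivity == 0.0 and m.specificity == 1.0

    def test_perfect_separation(self):
        m = metrics_at([9, 9], [8, 8], threshold=9)
        assert m.sensitivity == 1.0 and m.specificity == 1.0

    def test_monotonicity_invariants(self):
        """Sensitivity is non-increasing and specificity non-decreasing in
        the threshold on arbitrary score data."""
        rng = np.random.default_rng(11)
        for _ in range(20):
            cases = rng.integers(0, 15, size=rng.integers(1, 60))
            controls = rng.integers(0, 15, size=rng.integers(1, 60))
            table = sb.sens_spec_table(cases, controls)
            sens = [t.sensitivity for t in table]
            spec = [t.specificity for t in table]
            assert all(a >= b for a, b in zip(sens, sens[1:]))
            assert all(a <= b for a, b in zip(spec, spec[1:]))

    def test_ci_bounds_truncated(self):
        m = metrics_at([5], [4], threshold=5)
        for lo, hi in (m.sens_ci, m.spec_ci):
            assert 0.0 <= lo <= hi <= 1.0

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            sb.sens_spec_table([], [1])


def brute_force_auc(cases, controls) -> float:
    wins = 0.0
    for c in cases:
        for k in controls:
            wins += 1.0 if c > k else 0.5 if c == k else 0.0
    return wins / (len(cases) * len(controls))


class TestAUC:
    def test_identical_distributions(self):
        r = sb.auc([1, 2, 3], [1, 2, 3])
        assert r.auc == 0.5

    def test_complete_separation(self):
        assert sb.auc([4, 5], [1, 2]).auc == 1.0

    def test_small_example(self):
        assert sb.auc([2, 1], [1, 0]).auc == pytest.approx(0.875)

    def test_degenerate_sides(self):
        r = sb.auc([3, 3], [3, 3])
        assert r.auc == 0.5 and r.p_vs_half == 1.0

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        cases=st.lists(st.integers(0, 20), min_size=1, max_size=40),
        controls=st.lists(st.integers(0, 20), min_size=1, max_size=40),
    )
    def test_matches_brute_force_pair_counting(self, cases, controls):
        assert sb.auc(cases, controls).auc == pytest.approx(
            brute_force_auc(cases, controls), abs=1e-12
        )

    def test_matches_rank_sum_statistic(self):
        """Independent route: AUC = U / (m n) from the Mann-Whitney U."""
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(21)
        cases = rng.integers(0, 12, size=80)
        controls = rng.integers(0, 10, size=120)
        u = mannwhitneyu(cases, controls, alternative="two-sided").statistic
        assert sb.auc(cases, controls).auc == pytest.approx(u / (80 * 120))

    def test_equals_trapezoid_area_under_empirical_roc(self):
        """AUC equals the area under the ROC polygon built from the
        threshold table (with the (0,0)/(1,1) endpoints)."""
        rng = np.random.default_rng(5)
        cases = rng.integers(0, 10, size=100)
        controls = rng.integers(0, 8, size=90)
        table = sb.sens_spec_table(cases, controls)
        fpr = [1.0] + [1 - t.specificity for t in table] + [0.0]
        tpr = [1.0] + [t.sensitivity for t in table] + [0.0]
        area = -np.trapezoid(tpr, fpr)
        assert sb.auc(cases, controls).auc == pytest.approx(area, abs=1e-12)

    def test_null_test_significant_for_separated_data(self):
        r = sb.auc(np.arange(50, 100), np.arange(0, 60))
        assert r.p_vs_half < 1e-6


class TestSelectThreshold:
    def test_reference_male_threshold_is_9(self):
        table = load_reference_threshold_table("male")
        assert sb.select_threshold(table, max_fpr=0.20) == 9

    def test_reference_female_threshold_is_12(self):
        table = load_reference_threshold_table("female")
        assert sb.select_threshold(table, max_fpr=0.20) == 12

    def test_no_eligible_threshold_errors(self):
        table = sb.sens_spec_table([1, 1, 1], [1, 1, 1])
        eligible = [t for t in table if t.specificity > 0.8]
        if not eligible:
            with pytest.raises(ThresholdSelectionError):
                sb.select_threshold(table)

    def test_tie_breaks_to_lower_threshold(self):
        table = sb.sens_spec_table([12, 12], [1, 1])
        picked = sb.select_threshold(table)
        same_sens = [t.threshold for t in table
                     if t.specificity > 0.8 and t.sensitivity == 1.0]
        assert picked == min(same_sens)


class TestPPV:
    @pytest.mark.parametrize(
        "sens,spec,prior,expected",
        [(0.26, 0.87, 0.16, 0.28), (0.28, 0.76, 0.04, 0.05)],
    )
    def test_replication_worked_examples(self, sens, spec, prior, expected):
        assert round(sb.ppv(sens, spec, prior), 2) == expected

    def test_perfect_test(self):
        assert sb.ppv(1.0, 1.0, 0.3) == 1.0

    def test_undefined_when_nothing_positive(self):
        with pytest.raises(ValueError, match="undefined"):
            sb.ppv(0.0, 1.0, 0.1)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        sens=st.floats(0.05, 0.95),
        spec=st.floats(0.05, 0.95),
        prior=st.floats(0.05, 0.95),
        bump=st.floats(0.01, 0.04),
    )
    def test_monotonicity(self, sens, spec, prior, bump):
        base = sb.ppv(sens, spec, prior)
        assert sb.ppv(min(sens + bump, 1), spec, prior) > base
        assert sb.ppv(sens, min(spec + bump, 0.999), prior) > base
        assert sb.ppv(sens, spec, min(prior + bump, 0.999)) > base


class TestSplitRecurrence:
    @pytest.mark.parametrize(
        "overall,ratio,male,female",
        [(0.10, 4, 0.16, 0.04), (0.10, 1, 0.10, 0.10), (0.10, 9, 0.18, 0.02)],
    )
    def test_closed_form(self, overall, ratio, male, female):
        m, f = sb.split_recurrence(overall, ratio)
        assert m == pytest.approx(male) and f == pytest.approx(female)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(overall=st.floats(0.01, 0.4), ratio=st.floats(0.2, 4.5))
    def test_conserves_overall_as_equal_weight_mean(self, overall, ratio):
        m, f = sb.split_recurrence(overall, ratio)
        assert (m + f) / 2 == pytest.approx(overall, abs=1e-12)

    def test_male_risk_above_one_rejected(self):
        with pytest.raises(ValueError, match="exceeds 1"):
            sb.split_recurrence(0.6, 9)
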