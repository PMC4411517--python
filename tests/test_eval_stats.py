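"""Outcome arithmetic, summaries, and the hypothesis-test battery."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from clinsearch.corpus_model import CorpusError
from clinsearch.eval_stats import (
    NNRUndefinedError,
    SearchEvaluation,
    chi_square_proportions,
    evaluate_outcome,
    friedman_test,
    lilliefors_test,
    median_iqr,
    nnr,
    precision_at_k,
    stats_report,
    summarize,
    wald_ci,
)
from clinsearch.strategy_engine import SearchOutcome


class TestPrecisionAtK:
    def test_no_qualifying_gives_zero(self):
        n, q, p = precision_at_k(list(range(50)), set(), 50)
        assert (n, q, p) == (50, 0, 0.0)

    def test_five_of_fifty(self):
        n, q, p = precision_at_k(list(range(50)), set(range(5)), 50)
        assert p == 0.10

    def test_short_result_list_shrinks_denominator(self):
        n, q, p = precision_at_k(list(range(30)), set(range(3)), 50)
        assert (n, q, p) == (30, 3, 0.1)

    def test_parsed_citations_mode_uses_resolved_count(self):
        # 23 resolved citations from 50 entries, 1 qualifying
        n, q, p = precision_at_k(list(range(23)), {0}, 50,
                                 denominator_mode="parsed_citations")
        assert n == 23 and q == 1
        assert p == pytest.approx(1 / 23)

    def test_empty_denominator_gives_zero_precision(self):
        assert precision_at_k([], {1}, 50) == (0, 0, 0.0)


class TestNNR:
    @pytest.mark.parametrize("precision,expected", [
        (0.055, 18), (0.04, 25), (0.02, 50), (0.5, 2), (1.0, 1),
    ])
    def test_inverse_of_precision_rounded(self, precision, expected):
        assert nnr(precision) == expected

    def test_undefined_at_zero(self):
        with pytest.raises(NNRUndefinedError):
            nnr(0.0)

    @given(st.floats(0.01, 1.0))
    def test_rounding_bound(self, p):
        assert abs(nnr(p) - 1 / p) <= 0.5


class TestMedianIqr:
    @pytest.mark.parametrize("values,expected", [
        ([1, 2, 3, 4, 5], (3, 2, 4)),
        ([0, 0, 0, 10], (0, 0, 2.5)),  # type-7 linear interpolation
        ([7, 7, 7], (7, 7, 7)),
    ])
    def test_quartile_convention(self, values, expected):
        assert median_iqr(values) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(CorpusError):
            median_iqr([])


class TestWaldCI:
    def test_reproduces_reported_interval(self):
        assert wald_ci(round(0.73 * 312), 312) == (68, 78)

    def test_lower_bound_clipped_at_zero(self):
        lower, upper = wald_ci(0, 100)
        assert lower == 0

    def test_hand_computed_symmetric_case(self):
        # p=0.5, n=312: half-width 1.959964*sqrt(.25/312) = 0.05547 -> 44..56
        assert wald_ci(156, 312) == (44, 56)

    def test_width_shrinks_as_inverse_sqrt_n(self):
        def width(n):
            p = 0.3
            lo, hi = wald_ci(round(p * n), n)
            return hi - lo
        assert width(4 * 400) == pytest.approx(width(400) / 2, abs=2)

    def test_invalid_inputs(self):
        with pytest.raises(CorpusError):
            wald_ci(1, 0)
        with pytest.raises(CorpusError):
            wald_ci(5, 4)


class TestFriedman:
    def test_identical_columns_give_zero_statistic(self):
        matrix = [[0.1, 0.1, 0.1]] * 4
        stat, p, flags = friedman_test(matrix)
        assert stat == 0.0
        assert not any(any(row) for row in flags)

    def test_matches_brute_force_rank_formula_on_toy_matrix(self):
        matrix = np.array([[1, 2, 3], [2, 3, 1], [3, 1, 2], [1, 3, 2.0]])
        # untied rows: chi2 = 12/(n k (k+1)) sum Rj^2 - 3 n (k+1)
        ranks = np.apply_along_axis(sps.rankdata, 1, matrix)
        rj = ranks.sum(axis=0)
        expected = 12 / (4 * 3 * 4) * (rj ** 2).sum() - 3 * 4 * 4
        stat, _, _ = friedman_test(matrix)
        assert stat == pytest.approx(expected)

    def test_exhaustive_small_matrices_match_independent_oracle(self):
        """Tie-corrected statistic equals scipy's on every 3x3 matrix over a
        small value grid (mid-rank ties included)."""
        values = (0.0, 0.1, 0.2)
        checked = 0
        for cells in itertools.product(values, repeat=9):
            matrix = np.array(cells).reshape(3, 3)
            if all(len(set(row)) == 1 for row in matrix):
                continue  # fully tied: scipy divides by zero, we define 0
            stat, p, _ = friedman_test(matrix)
            ref_stat, ref_p = sps.friedmanchisquare(*matrix.T)
            assert stat == pytest.approx(ref_stat, abs=1e-10)
            assert p == pytest.approx(ref_p, abs=1e-10)
            checked += 1
        assert checked > 10_000

    def test_dominating_strategy_flagged_in_posthoc(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0, 0.1, size=(60, 3))
        base[:, 0] += 0.5  # one strategy dominates every question
        stat, p, flags = friedman_test(base)
        assert p < 0.05
        assert flags[0][1] and flags[0][2]
        assert flags == tuple(tuple(row) for row in zip(*flags))  # symmetric

    def test_incomplete_matrix_rejected(self):
        with pytest.raises(CorpusError):
            friedman_test([[1.0, np.nan], [2.0, 3.0]])


class TestChiSquare:
    def test_equal_proportions_zero_statistic(self):
        stat, p = chi_square_proportions([30, 30], [100, 100])
        assert stat == 0.0

    def test_matches_closed_form_two_by_two(self):
        a, b, n1, n2 = 30, 60, 100, 100
        stat, _ = chi_square_proportions([a, b], [n1, n2])
        # closed-form Pearson statistic for a 2x2 table
        n = n1 + n2
        expected = (n * (a * (n2 - b) - b * (n1 - a)) ** 2
                    / ((a + b) * (n - a - b) * n1 * n2))
        assert stat == pytest.approx(expected)

    def test_zero_group_size_rejected(self):
        with pytest.raises(CorpusError):
            chi_square_proportions([0, 1], [0, 10])

    def test_degenerate_margins_define_zero(self):
        assert chi_square_proportions([0, 0], [10, 10]) == (0.0, 1.0)


class TestLilliefors:
    def test_null_rejection_rate_near_alpha(self):
        """Under a true normal null the MC p-value rejects at ~alpha."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_rep = 200
        for i in range(n_rep):
            sample = rng.normal(size=60)
            p = lilliefors_test(sample, n_mc=200, seed=1000 + i)
            rejections += p < 0.05
        rate = rejections / n_rep
        assert abs(rate - 0.05) <= 3 * math.sqrt(0.05 * 0.95 / n_rep) + 0.01

    def test_zero_inflated_precision_sample_rejects_strongly(self):
        rng = np.random.default_rng(7)
        sample = np.where(rng.random(312) < 0.55, 0.0, rng.uniform(0.02, 0.2, 312))
        assert lilliefors_test(sample, n_mc=2000, seed=3) < 0.001

    def test_statistic_agrees_with_statsmodels(self):
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors
        rng = np.random.default_rng(5)
        sample = rng.exponential(size=80)
        p_ours = lilliefors_test(sample, n_mc=5000, seed=11)
        _, p_ref = sm_lilliefors(sample, dist="norm")
        # table-interpolated vs Monte-Carlo p: agreement within a small band
        assert p_ours == pytest.approx(p_ref, abs=0.02)

    def test_constant_sample_rejected(self):
        with pytest.raises(CorpusError):
            lilliefors_test([2.0, 2.0, 2.0, 2.0])


def _ev(qid, strategy, n_cons, n_qual, iterations=None):
    return SearchEvaluation(
        question_id=qid, strategy=strategy, n_considered=n_cons,
        n_qualifying=n_qual, precision=(n_qual / n_cons if n_cons else 0.0),
        at_least_one=n_qual >= 1, iterations_used=iterations)


class TestSummarize:
    def test_single_question_summary_equals_its_values(self):
        [summary], _ = summarize([_ev("q1", "narrow", 50, 5)])
        assert summary.median_precision == 0.1
        assert summary.nnr == 10
        assert summary.prop_at_least_one == 1.0

    def test_mean_of_fractions_differs_from_pooled_ratio(self):
        """0/10 and 2/2: the mean precision is 0.5, the pooled ratio 2/12."""
        evals = [_ev("q1", "web", 10, 0), _ev("q2", "web", 2, 2)]
        [summary], _ = summarize(evals)
        assert summary.mean_precision == 0.5
        pooled = sum(e.n_qualifying for e in evals) / sum(e.n_considered for e in evals)
        assert pooled == pytest.approx(2 / 12)
        assert summary.mean_precision != pytest.approx(pooled)

    def test_nnr_undefined_at_median_zero(self):
        evals = [_ev(f"q{i}", "web", 50, 0) for i in range(3)]
        [summary], _ = summarize(evals)
        assert summary.nnr is None

    def test_permutation_invariant_in_question_order(self):
        evals = [_ev(f"q{i}", "broad", 50, i % 4) for i in range(12)]
        a, _ = summarize(evals)
        b, _ = summarize(list(reversed(evals)))
        assert a == b

    def test_figure_grouping_by_iterations_used(self):
        evals = [_ev("q1", "experimental", 50, 1, iterations=1),
                 _ev("q2", "experimental", 50, 5, iterations=4),
                 _ev("q3", "experimental", 50, 10, iterations=4)]
        _, fig2 = summarize(evals)
        assert list(fig2["iterations_used"]) == [1, 4]
        assert list(fig2["n"]) == [1, 2]
        assert fig2.loc[fig2["iterations_used"] == 4, "mean_precision"].iloc[0] \
            == pytest.approx(0.15)


class TestStatsReport:
    def test_complete_battery_on_synthetic_evaluations(self):
        rng = np.random.default_rng(3)
        evals = []
        for i in range(40):
            for s, boost in (("experimental", 4), ("narrow", 1), ("broad", 0)):
                n_qual = int(rng.integers(0, 3)) + boost
                evals.append(_ev(f"q{i:02d}", s, 50, n_qual))
        report = stats_report(evals, n_mc=200, seed=0)
        assert report.friedman_p < 0.001
        assert report.chisq_p < 0.05
        assert set(report.normality_p) == {"experimental", "narrow", "broad"}
        i = report.strategies.index("experimental")
        j = report.strategies.index("broad")
        assert report.posthoc_flags[i][j]

    def test_incomplete_design_rejected(self):
        evals = [_ev("q1", "narrow", 50, 1), _ev("q2", "broad", 50, 1)]
        with pytest.raises(CorpusError):
            stats_report(evals)
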