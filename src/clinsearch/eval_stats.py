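"""Quantitative outcomes and hypothesis tests for strategy comparison.

Outcomes per question and strategy: precision at k (the proportion of the
first k = 50 examined results that are relevant, high-quality citations —
precision is 0 when nothing qualifies), the count of qualifying citations,
and whether at least one was found.  Per strategy these are summarized as
median (IQR) and mean, the proportion of searches with >= 1 hit with a Wald
confidence interval, and the number needed to read (NNR), the inverse of the
median precision rounded to the nearest integer.

Two precision denominators exist because the web strategies do not return
citations directly: for Boolean strategies the denominator is the number of
ranked citations examined (<= k); for web strategies it is the number of
PubMed citations resolved from identifiers parsed out of the first k result
entries.  The mean of per-search fractions is *not* the ratio of mean
numerator to mean denominator; summaries always average the per-search
fractions.

Hypothesis tests: Friedman's rank-sum test across strategies (questions as
blocks, mid-rank ties, tie-corrected chi-square reference) with a
Nemenyi-style critical-difference post hoc on rank sums; Pearson chi-square
(no continuity correction) for the dichotomous >= 1-hit rates; and a
Lilliefors (Kolmogorov–Smirnov with estimated mean/sd) normality test whose
p-value is calibrated by Monte Carlo under a fixed seed.

Quartiles use linear interpolation between order statistics (R type 7).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .corpus_model import CorpusError
from .strategy_engine import SearchOutcome

DENOMINATOR_MODES = ("rank_k", "parsed_citations")


class NNRUndefinedError(ValueError):
    """NNR is undefined when the (median) precision is zero."""


@dataclass(frozen=True)
class SearchEvaluation:
    """Per-question, per-strategy outcome of the reference-standard evaluation."""

    question_id: str
    strategy: str
    n_considered: int
    n_qualifying: int
    precision: float
    at_least_one: bool
    iterations_used: int | None = None

    def __post_init__(self) -> None:
        if self.n_qualifying > self.n_considered:
            raise CorpusError("n_qualifying cannot exceed n_considered")


@dataclass(frozen=True)
class StrategySummary:
    """One strategy's row of the comparison table."""

    strategy: str
    n_questions: int
    median_precision: float
    precision_iqr: tuple[float, float]
    mean_precision: float
    median_count: float
    count_iqr: tuple[float, float]
    mean_count: float
    prop_at_least_one: float
    prop_ci: tuple[float, float]  # whole-percent bounds
    nnr: int | None


@dataclass(frozen=True)
class StatsReport:
    """Hypothesis-test results across strategies."""

    strategies: tuple[str, ...]
    friedman_statistic: float
    friedman_p: float
    posthoc_flags: tuple[tuple[bool, ...], ...]
    chisq_statistic: float
    chisq_p: float
    normality_p: Mapping[str, float]


# ---------------------------------------------------------------------------
# Per-search outcomes
# ---------------------------------------------------------------------------

def precision_at_k(ranked_pmids: Sequence[int], qualifying: set[int], k: int,
                   denominator_mode: str = "rank_k") -> tuple[int, int, float]:
    """(n_considered, n_qualifying, precision) over the first-k results.

    ``rank_k``: the first min(k, available) ranked citations are examined and
    form the denominator.  ``parsed_citations``: ``ranked_pmids`` are the
    citations resolved from the first k web-result entries; all of them form
    the denominator.  Precision is 0 when the denominator is 0.
    """
    if k < 1:
        raise CorpusError("k must be >= 1")
    if denominator_mode not in DENOMINATOR_MODES:
        raise CorpusError(f"denominator_mode must be one of {DENOMINATOR_MODES}")
    considered = list(ranked_pmids[:k])
    n_considered = len(considered)
    n_qualifying = sum(1 for p in considered if p in qualifying)
    precision = n_qualifying / n_considered if n_considered else 0.0
    return n_considered, n_qualifying, precision


def evaluate_outcome(outcome: SearchOutcome, qualifying: set[int], k: int = 50,
                     denominator_mode: str = "rank_k") -> SearchEvaluation:
    """Adjudicate one strategy run against the question's qualifying set."""
    n_considered, n_qualifying, precision = precision_at_k(
        outcome.pmids, qualifying, k, denominator_mode
    )
    return SearchEvaluation(
        question_id=outcome.question_id,
        strategy=outcome.strategy,
        n_considered=n_considered,
        n_qualifying=n_qualifying,
        precision=precision,
        at_least_one=n_qualifying >= 1,
        iterations_used=(outcome.iteration_returned
                         if outcome.strategy == "experimental" else None),
    )


def nnr(precision: float) -> int:
    """Number needed to read: 1/precision, rounded half away from zero."""
    if precision <= 0:
        raise NNRUndefinedError("NNR is undefined at precision 0")
    if precision > 1:
        raise CorpusError("precision must be in (0, 1]")
    return int(math.floor(1.0 / precision + 0.5))


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """(median, q1, q3) with linear interpolation between order statistics."""
    if len(values) == 0:
        raise CorpusError("median_iqr needs a non-empty list")
    arr = np.asarray(values, dtype=float)
    med, q1, q3 = np.quantile(arr, [0.5, 0.25, 0.75])  # type-7 interpolation
    return float(med), float(q1), float(q3)


def wald_ci(successes: int, n: int, conf: float = 0.95) -> tuple[int, int]:
    """Normal-approximation CI for a proportion, as whole-percent bounds.

    p-hat +/- z * sqrt(p-hat (1 - p-hat) / n), clipped to [0, 1] and rounded
    to whole percent; no continuity correction.
    """
    if n < 1:
        raise CorpusError("wald_ci needs n >= 1")
    if not 0 <= successes <= n:
        raise CorpusError("successes must be in [0, n]")
    p = successes / n
    z = sps.norm.ppf(0.5 + conf / 2)
    half = z * math.sqrt(p * (1 - p) / n)
    lower = max(0.0, p - half)
    upper = min(1.0, p + half)
    return int(round(lower * 100)), int(round(upper * 100))


# ---------------------------------------------------------------------------
# Hypothesis tests
# ---------------------------------------------------------------------------

def friedman_test(matrix: Sequence[Sequence[float]], alpha: float = 0.05
                  ) -> tuple[float, float, tuple[tuple[bool, ...], ...]]:
    """Friedman's rank-sum test over a complete questions x strategies matrix.

    Within-question mid-rank ties; the chi-square statistic carries the
    standard tie correction.  The post hoc flags pairs of strategies whose
    mean-rank difference exceeds the Nemenyi critical difference at ``alpha``.
    """
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise CorpusError("friedman_test needs a complete matrix, >= 2 x 2")
    if np.isnan(arr).any():
        raise CorpusError("friedman_test requires a complete matrix")
    n, k = arr.shape
    ranks = sps.rankdata(arr, axis=1)
    rank_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * float((rank_sums ** 2).sum()) - 3.0 * n * (k + 1)
    # tie correction over within-block tie groups
    ties = 0.0
    for row in arr:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts ** 3 - counts).sum())
    correction = 1.0 - ties / (n * k * (k * k - 1))
    if correction <= 0:  # every block fully tied
        stat, p = 0.0, 1.0
    else:
        stat /= correction
        p = float(sps.chi2.sf(stat, k - 1))
    mean_ranks = rank_sums / n
    q = sps.studentized_range.ppf(1 - alpha, k, np.inf)
    cd = (q / math.sqrt(2)) * math.sqrt(k * (k + 1) / (6.0 * n))
    flags = tuple(
        tuple(bool(i != j and abs(mean_ranks[i] - mean_ranks[j]) >= cd)
              for j in range(k))
        for i in range(k)
    )
    return float(stat), float(p), flags


def chi_square_proportions(successes: Sequence[int], ns: Sequence[int]
                           ) -> tuple[float, float]:
    """Pearson chi-square on the strategies x {>=1 hit, 0 hits} table."""
    if len(successes) != len(ns) or len(ns) < 2:
        raise CorpusError("need matching success/n lists of length >= 2")
    if any(n < 1 for n in ns):
        raise CorpusError("all group sizes must be >= 1")
    if any(not 0 <= s <= n for s, n in zip(successes, ns)):
        raise CorpusError("successes must be within [0, n] per group")
    table = np.array([[s, n - s] for s, n in zip(successes, ns)], dtype=float)
    if (table.sum(axis=0) == 0).any():  # degenerate margin: identical rates
        return 0.0, 1.0
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def lilliefors_test(values: Sequence[float], n_mc: int = 1000,
                    seed: int = 0) -> float:
    """Normality test with estimated mean/sd; Monte-Carlo p-value.

    The statistic is the two-sided Kolmogorov–Smirnov distance between the
    empirical CDF and the normal fitted to the sample; the null distribution
    of the statistic (which the plain KS tables do not cover once parameters
    are estimated) is simulated with ``n_mc`` standard-normal replicates.
    """
    arr = np.sort(np.asarray(values, dtype=float))
    n = arr.size
    if n < 4:
        raise CorpusError("lilliefors_test needs >= 4 values")
    if np.allclose(arr, arr[0]):
        raise CorpusError("lilliefors_test is undefined for a constant sample")

    def ks_stat(sample_sorted: np.ndarray) -> np.ndarray:
        m = sample_sorted.mean(axis=-1, keepdims=True)
        s = sample_sorted.std(axis=-1, ddof=1, keepdims=True)
        cdf = sps.norm.cdf((sample_sorted - m) / s)
        i = np.arange(1, n + 1)
        d_plus = (i / n - cdf).max(axis=-1)
        d_minus = (cdf - (i - 1) / n).max(axis=-1)
        return np.maximum(d_plus, d_minus)

    d_obs = float(ks_stat(arr))
    rng = np.random.default_rng(seed)
    null = ks_stat(np.sort(rng.standard_normal((n_mc, n)), axis=-1))
    return float((1 + (null >= d_obs).sum()) / (n_mc + 1))


# ---------------------------------------------------------------------------
# Summaries and reports
# ---------------------------------------------------------------------------

def summarize(evaluations: Sequence[SearchEvaluation], conf: float = 0.95
              ) -> tuple[list[StrategySummary], pd.DataFrame]:
    """Per-strategy summary rows plus the precision-by-iterations grouping.

    The grouping (experimental strategy only) breaks the precision
    distribution down by the number of iterations the escalation used.
    """
    if not evaluations:
        raise CorpusError("summarize needs at least one evaluation")
    summaries: list[StrategySummary] = []
    by_strategy: dict[str, list[SearchEvaluation]] = {}
    for ev in evaluations:
        by_strategy.setdefault(ev.strategy, []).append(ev)
    # canonical ordering makes the summary permutation-invariant
    for strategy in sorted(by_strategy):
        evs = sorted(by_strategy[strategy], key=lambda e: e.question_id)
        precisions = [ev.precision for ev in evs]
        counts = [ev.n_qualifying for ev in evs]
        med_p, q1_p, q3_p = median_iqr(precisions)
        med_c, q1_c, q3_c = median_iqr(counts)
        hits = sum(ev.at_least_one for ev in evs)
        summaries.append(StrategySummary(
            strategy=strategy,
            n_questions=len(evs),
            median_precision=med_p,
            precision_iqr=(q1_p, q3_p),
            mean_precision=float(np.mean(precisions)),
            median_count=med_c,
            count_iqr=(q1_c, q3_c),
            mean_count=float(np.mean(counts)),
            prop_at_least_one=hits / len(evs),
            prop_ci=wald_ci(hits, len(evs), conf),
            nnr=(nnr(med_p) if med_p > 0 else None),
        ))
    grouped_rows = []
    for ev in evaluations:
        if ev.strategy == "experimental" and ev.iterations_used is not None:
            grouped_rows.append({"iterations_used": ev.iterations_used,
                                 "precision": ev.precision})
    if grouped_rows:
        fig2 = (pd.DataFrame(grouped_rows)
                .groupby("iterations_used")["precision"]
                .agg(n="size", mean_precision="mean", median_precision="median")
                .reset_index())
    else:
        fig2 = pd.DataFrame(columns=["iterations_used", "n", "mean_precision",
                                     "median_precision"])
    return summaries, fig2


def stats_report(evaluations: Sequence[SearchEvaluation],
                 strategies: Sequence[str] | None = None,
                 alpha: float = 0.05, n_mc: int = 1000,
                 seed: int = 0) -> StatsReport:
    """Run the full test battery on a complete per-question evaluation set."""
    df = pd.DataFrame([{
        "question_id": ev.question_id, "strategy": ev.strategy,
        "precision": ev.precision, "at_least_one": ev.at_least_one,
    } for ev in evaluations])
    if strategies is None:
        strategies = sorted(df["strategy"].unique())
    wide = df.pivot(index="question_id", columns="strategy", values="precision")
    wide = wide[list(strategies)]
    if wide.isna().any().any():
        raise CorpusError("stats_report needs every strategy run on every question")
    stat, p, flags = friedman_test(wide.to_numpy(), alpha=alpha)
    hits = df.groupby("strategy")["at_least_one"].sum()
    ns = df.groupby("strategy")["at_least_one"].size()
    chisq, chisq_p = chi_square_proportions(
        [int(hits[s]) for s in strategies], [int(ns[s]) for s in strategies]
    )
    normality = {}
    for i, s in enumerate(strategies):
        vals = wide[s].to_numpy()
        try:
            normality[s] = lilliefors_test(vals, n_mc=n_mc, seed=seed + i)
        except CorpusError:
            normality[s] = float("nan")  # constant column: normality untestable
    return StatsReport(
        strategies=tuple(strategies),
        friedman_statistic=stat,
        friedman_p=p,
        posthoc_flags=flags,
        chisq_statistic=chisq,
        chisq_p=chisq_p,
        normality_p=normality,
    )


def summary_table(summaries: Sequence[StrategySummary]) -> pd.DataFrame:
    """Render summaries as a tidy table (percent-scaled precision columns)."""
    return pd.DataFrame([{
        "strategy": s.strategy,
        "n": s.n_questions,
        "median_precision_pct": round(100 * s.median_precision, 1),
        "iqr_precision_pct": f"{100 * s.precision_iqr[0]:g}-{100 * s.precision_iqr[1]:g}",
        "mean_precision_pct": round(100 * s.mean_precision, 1),
        "median_count": s.median_count,
        "iqr_count": f"{s.count_iqr[0]:g}-{s.count_iqr[1]:g}",
        "mean_count": round(s.mean_count, 1),
        "prop_at_least_one_pct": round(100 * s.prop_at_least_one),
        "ci_at_least_one_pct": f"{s.prop_ci[0]}-{s.prop_ci[1]}",
        "nnr": s.nnr if s.nnr is not None else "",
    } for s in summaries])
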