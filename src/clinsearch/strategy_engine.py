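"""Search strategies over the backend contract.

The experimental strategy escalates through up to five progressively more
restrictive query iterations and returns the last iteration that still
retrieved at least the target number of citations (default 50, the futility
point beyond which a searcher will not scan).  The iteration ladder:

1. base Boolean query, no filter;
2. sensitive therapy filter OR systematic-review subset; publication types
   review/letter/editorial excluded; abstract required;
3. as 2 but with the specific therapy filter;
4. as 3 plus restriction to a core-journal whitelist;
5. as 4 plus restriction of base terms to the MeSH major field.

Because every step only adds conjunctive restrictions, per-iteration hit
counts are non-increasing, and the engine can stop at the first iteration
that falls below the target: the result is identical to evaluating all five.
When even iteration 1 retrieves fewer than the target, its (broadest)
results are returned rather than nothing.

The single-filter comparators are one-shot runs of the specific ("narrow")
or sensitive ("broad") therapy filter with no other restrictions.

This module never consults the quality metadata used by the reference
standard (no incorporation bias).
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus_model import ClinicalQuestion, CorpusError
from .query_builder import BaseQuery, build_base_query
from .retrieval_index import HedgeKind, QueryPlan, SearchBackend

EXCLUDED_PUB_TYPES = frozenset({"Review", "Letter", "Editorial"})

MAX_ITERATION_LEVELS = 5


class StrategyError(RuntimeError):
    """A backend failure, annotated with the question being searched."""


@dataclass(frozen=True)
class StrategyConfig:
    """Run parameters shared by all strategies.

    ``target_count`` is the futility threshold of the stopping rule;
    ``retmax`` is how many ranked results are kept per search;
    ``journal_whitelist`` is the core-journal list used from iteration 4 on
    (a stand-in for the 106-journal core clinical list).
    """

    target_count: int = 50
    max_iterations: int = 5
    retmax: int = 50
    journal_whitelist: frozenset[str] | None = None

    def __post_init__(self) -> None:
        if self.target_count < 1:
            raise CorpusError("target_count must be >= 1")
        if not 1 <= self.max_iterations <= MAX_ITERATION_LEVELS:
            raise CorpusError(
                f"max_iterations must be in 1..{MAX_ITERATION_LEVELS}"
            )
        if self.retmax < 1:
            raise CorpusError("retmax must be >= 1")


@dataclass(frozen=True)
class SearchOutcome:
    """Per-question result of one strategy run."""

    question_id: str
    strategy: str
    iteration_returned: int
    per_iteration_counts: tuple[int, ...]
    pmids: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_iteration_counts", tuple(self.per_iteration_counts))
        object.__setattr__(self, "pmids", tuple(self.pmids))


def iteration_plan(base: BaseQuery, level: int,
                   journal_whitelist: frozenset[str] | None = None) -> QueryPlan:
    """Build the query plan for one iteration level (1..5) of the ladder."""
    if not 1 <= level <= MAX_ITERATION_LEVELS:
        raise CorpusError(f"iteration level must be in 1..{MAX_ITERATION_LEVELS}, got {level}")
    if level == 1:
        return QueryPlan(base=base)
    if level >= 4 and journal_whitelist is None:
        raise CorpusError(f"iteration level {level} requires a journal whitelist")
    hedge = HedgeKind.SENSITIVE_OR_SYSREV if level == 2 else HedgeKind.SPECIFIC_OR_SYSREV
    return QueryPlan(
        base=base,
        hedge=hedge,
        exclude_pub_types=EXCLUDED_PUB_TYPES,
        require_abstract=True,
        journal_whitelist=journal_whitelist if level >= 4 else None,
        mesh_major_only=(level >= 5),
    )


def stopping_level(counts, target: int) -> int:
    """The iteration the escalation returns for a per-level count profile.

    The greatest level whose count reaches ``target``; level 1 when none does.
    """
    best = 1
    for level, count in enumerate(counts, start=1):
        if count >= target:
            best = level
    return best


def run_experimental(question: ClinicalQuestion, backend: SearchBackend,
                     config: StrategyConfig = StrategyConfig()) -> SearchOutcome:
    """Run the iterative strategy for one question.

    Escalates from level 1, stopping at the first level that retrieves fewer
    than ``config.target_count`` citations (counts are non-increasing, so no
    later level can recover); returns the results of the last level at or
    above the target, or level 1's results if none reached it.
    """
    base = build_base_query(question)
    counts: list[int] = []
    returned_level = 1
    returned_pmids: tuple[int, ...] = ()
    for level in range(1, config.max_iterations + 1):
        plan = iteration_plan(base, level, config.journal_whitelist)
        try:
            total, pmids = backend.execute(plan, config.retmax)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise StrategyError(
                f"backend failed at iteration {level} for question "
                f"{question.question_id!r}: {exc}"
            ) from exc
        counts.append(total)
        if total >= config.target_count or level == 1:
            returned_level, returned_pmids = level, tuple(pmids)
        if total < config.target_count:
            break
    assert returned_level == stopping_level(counts, config.target_count)
    return SearchOutcome(
        question_id=question.question_id,
        strategy="experimental",
        iteration_returned=returned_level,
        per_iteration_counts=tuple(counts),
        pmids=returned_pmids,
    )


_SINGLE_FILTER_HEDGES = {
    "narrow": HedgeKind.SPECIFIC_ONLY,
    "broad": HedgeKind.SENSITIVE_ONLY,
}


def run_single_filter(question: ClinicalQuestion, backend: SearchBackend,
                      kind: str,
                      config: StrategyConfig = StrategyConfig()) -> SearchOutcome:
    """Run one clinical-queries therapy filter (narrow=specific, broad=sensitive)."""
    if kind not in _SINGLE_FILTER_HEDGES:
        raise CorpusError(f"single-filter kind must be narrow|broad, got {kind!r}")
    plan = QueryPlan(base=build_base_query(question), hedge=_SINGLE_FILTER_HEDGES[kind])
    try:
        total, pmids = backend.execute(plan, config.retmax)
    except Exception as exc:  # noqa: BLE001
        raise StrategyError(
            f"backend failed for question {question.question_id!r}: {exc}"
        ) from exc
    return SearchOutcome(
        question_id=question.question_id,
        strategy=kind,
        iteration_returned=1,
        per_iteration_counts=(total,),
        pmids=tuple(pmids),
    )
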