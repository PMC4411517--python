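"""Offline Boolean retrieval over citation records.

Implements term matching against MeSH headings, entry terms and title/abstract
text; the methodological hedge predicates (sensitive/specific therapy filters
and a systematic-review subset); conjunctive query plans with
publication-type, abstract, journal and MeSH-major restrictions; and
deterministic date-descending ranking.  The :class:`SearchBackend` protocol is
the contract any search source (offline index, live Entrez adapter) must
satisfy.

The hedge definitions are record-level predicates rather than PubMed query
strings so the engine runs fully offline; they are shipped as a module-level
table (``HEDGE_PREDICATES``) that callers may override, e.g. to substitute
verbatim clinical-queries filter strings for live use.

Tokenization is deliberately simple and deterministic: lowercase, split on
non-alphanumeric characters; a phrase matches when its tokens occur as a
contiguous subsequence.  The only stemming anywhere is the ``random*`` prefix
rule of the sensitive filter.

Note this module never reads the quality fields (the synoptic-review and
editorial flags): search must stay independent of the reference standard to
avoid incorporation bias.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Protocol, Sequence

from .corpus_model import CitationRecord, CorpusError
from .query_builder import BaseQuery

_TOKEN_RE = re.compile(r"[^a-z0-9]+")

#: Journal title used by the systematic-review subset predicate.
COCHRANE_JOURNAL = "Cochrane Database of Systematic Reviews"


def tokenize(text: str | None) -> tuple[str, ...]:
    """Lowercase and split on non-alphanumeric runs; empty tokens dropped."""
    if not text:
        return ()
    return tuple(t for t in _TOKEN_RE.split(text.lower()) if t)


def contains_phrase(tokens: Sequence[str], phrase: Sequence[str]) -> bool:
    """True when ``phrase`` occurs as a contiguous token subsequence."""
    n, m = len(tokens), len(phrase)
    if m == 0 or m > n:
        return False
    first = phrase[0]
    for i in range(n - m + 1):
        if tokens[i] == first and tuple(tokens[i:i + m]) == tuple(phrase):
            return True
    return False


def normalize_journal(name: str) -> str:
    return " ".join(name.split()).lower()


class HedgeKind(str, Enum):
    """Methodological filter applied on top of the Boolean base query."""

    NONE = "none"
    SENSITIVE_OR_SYSREV = "sensitive_or_sysrev"
    SPECIFIC_OR_SYSREV = "specific_or_sysrev"
    SENSITIVE_ONLY = "sensitive_only"
    SPECIFIC_ONLY = "specific_only"
    SYSREV_ONLY = "sysrev_only"


@dataclass(frozen=True)
class QueryPlan:
    """A fully specified Boolean query: base terms plus iteration restrictions.

    When ``mesh_major_only`` is set, base terms are matched only against
    major-topic MeSH descriptors/entry terms (the text-word path is off,
    mirroring a major-field restriction).
    """

    base: BaseQuery
    hedge: HedgeKind = HedgeKind.NONE
    exclude_pub_types: frozenset[str] = frozenset()
    require_abstract: bool = False
    journal_whitelist: frozenset[str] | None = None
    mesh_major_only: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "exclude_pub_types", frozenset(self.exclude_pub_types))
        if self.journal_whitelist is not None:
            object.__setattr__(
                self, "journal_whitelist",
                frozenset(normalize_journal(j) for j in self.journal_whitelist),
            )


class SearchBackend(Protocol):
    """Contract for a search source: deterministic, date-descending results."""

    def execute(self, plan: QueryPlan, retmax: int) -> tuple[int, list[int]]:
        """Return (total matching count, top-``retmax`` PMIDs in rank order)."""
        ...


# ---------------------------------------------------------------------------
# Cached per-record view
# ---------------------------------------------------------------------------

class _RecordView:
    """Pre-tokenized view of one record; built once per index."""

    __slots__ = ("record", "text_tokens", "mesh_phrases", "major_phrases",
                 "subheadings", "journal_norm", "has_random_prefix")

    def __init__(self, record: CitationRecord) -> None:
        self.record = record
        self.text_tokens = tokenize(record.title) + ("\x00",) + tokenize(record.abstract)
        mesh_phrases: set[tuple[str, ...]] = set()
        major_phrases: set[tuple[str, ...]] = set()
        subheadings: set[str] = set()
        for m in record.mesh_terms:
            phrases = {tokenize(m.descriptor)} | {tokenize(t) for t in m.entry_terms}
            mesh_phrases |= phrases
            if m.is_major:
                major_phrases |= phrases
            subheadings |= {s.lower() for s in m.subheadings}
        self.mesh_phrases = mesh_phrases
        self.major_phrases = major_phrases
        self.subheadings = subheadings
        self.journal_norm = normalize_journal(record.journal)
        self.has_random_prefix = any(t.startswith("random") for t in self.text_tokens)


def _view(record: CitationRecord | _RecordView) -> _RecordView:
    return record if isinstance(record, _RecordView) else _RecordView(record)


# ---------------------------------------------------------------------------
# Term matching
# ---------------------------------------------------------------------------

def match_term(record: CitationRecord | _RecordView, term: str,
               major_only: bool = False) -> bool:
    """Does ``term`` (normalized, comma-free) match the record?

    Without ``major_only``: the term equals a MeSH descriptor or entry term
    (case-insensitive, token-wise) or occurs as a contiguous token phrase in
    the title or abstract.  With ``major_only``: only major-topic MeSH
    descriptors/entry terms are consulted.
    """
    view = _view(record)
    phrase = tokenize(term)
    if not phrase:
        return False
    if major_only:
        return phrase in view.major_phrases
    if phrase in view.mesh_phrases:
        return True
    return contains_phrase(view.text_tokens, phrase)


# ---------------------------------------------------------------------------
# Hedge predicates
# ---------------------------------------------------------------------------

def _sensitive(view: _RecordView) -> bool:
    rec = view.record
    if rec.pub_types & {"Randomized Controlled Trial", "Clinical Trial"}:
        return True
    if view.has_random_prefix:
        return True
    if {("random", "allocation"), ("clinical", "trials", "as", "topic")} & view.mesh_phrases:
        return True
    return "therapeutic use" in view.subheadings


def _specific(view: _RecordView) -> bool:
    rec = view.record
    if "Randomized Controlled Trial" in rec.pub_types:
        return True
    toks = set(view.text_tokens)
    return {"randomized", "controlled", "trial"} <= toks


def _sysrev(view: _RecordView) -> bool:
    rec = view.record
    if "Meta-Analysis" in rec.pub_types:
        return True
    if contains_phrase(view.text_tokens, ("systematic", "review")):
        return True
    return view.journal_norm == normalize_journal(COCHRANE_JOURNAL)


#: Named hedge predicate table; replaceable for live-PubMed use.
HEDGE_PREDICATES: dict[HedgeKind, Callable[[_RecordView], bool]] = {
    HedgeKind.NONE: lambda view: True,
    HedgeKind.SENSITIVE_ONLY: _sensitive,
    HedgeKind.SPECIFIC_ONLY: _specific,
    HedgeKind.SYSREV_ONLY: _sysrev,
    HedgeKind.SENSITIVE_OR_SYSREV: lambda view: _sensitive(view) or _sysrev(view),
    HedgeKind.SPECIFIC_OR_SYSREV: lambda view: _specific(view) or _sysrev(view),
}


def hedge_predicate(record: CitationRecord | _RecordView, kind: HedgeKind) -> bool:
    """Evaluate one methodological filter on a record."""
    return HEDGE_PREDICATES[HedgeKind(kind)](_view(record))


# ---------------------------------------------------------------------------
# Plan evaluation and the offline index
# ---------------------------------------------------------------------------

def evaluate_plan(record: CitationRecord | _RecordView, plan: QueryPlan) -> bool:
    """Conjunction of base-term matching, hedge, and the plan's restrictions."""
    view = _view(record)
    rec = view.record
    if plan.require_abstract and not rec.abstract:
        return False
    if plan.exclude_pub_types & rec.pub_types:
        return False
    if plan.journal_whitelist is not None and view.journal_norm not in plan.journal_whitelist:
        return False
    if not all(match_term(view, t, plan.mesh_major_only) for t in plan.base.terms):
        return False
    return hedge_predicate(view, plan.hedge)


class OfflineIndex:
    """In-memory search backend over a citation corpus.

    Satisfies the :class:`SearchBackend` contract: results are ranked by
    publication date descending, ties broken by PMID descending, so repeated
    identical queries return identical output.
    """

    def __init__(self, corpus: Sequence[CitationRecord]) -> None:
        seen: set[int] = set()
        for rec in corpus:
            if rec.pmid in seen:
                raise CorpusError(f"duplicate PMID {rec.pmid} in corpus")
            seen.add(rec.pmid)
        views = [_RecordView(r) for r in corpus]
        views.sort(key=lambda v: (v.record.pub_date, v.record.pmid), reverse=True)
        self._views = views
        self._by_pmid = {v.record.pmid: v.record for v in views}

    def __len__(self) -> int:
        return len(self._views)

    def execute(self, plan: QueryPlan, retmax: int) -> tuple[int, list[int]]:
        return execute_offline(self, plan, retmax)

    def get(self, pmid: int) -> CitationRecord | None:
        return self._by_pmid.get(pmid)


def execute_offline(index: OfflineIndex, plan: QueryPlan,
                    retmax: int) -> tuple[int, list[int]]:
    """Run a plan against the offline index.

    Returns the total matching count and the top-``retmax`` PMIDs in
    date-descending order (PMID-descending tie-break).
    """
    if retmax < 1:
        raise CorpusError(f"retmax must be >= 1, got {retmax}")
    total = 0
    top: list[int] = []
    for view in index._views:  # views are pre-sorted in rank order
        if evaluate_plan(view, plan):
            total += 1
            if len(top) < retmax:
                top.append(view.record.pmid)
    return total, top


def read_journal_whitelist(path) -> frozenset[str]:
    """Read a journal whitelist: plain text, one journal title per line."""
    with open(path, encoding="utf-8") as fh:
        return frozenset(
            line.strip() for line in fh if line.strip() and not line.startswith("#")
        )
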