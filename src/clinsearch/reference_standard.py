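"""Relevance and quality adjudication of retrieved citations.

A citation answers a question when it is *relevant* — it carries every
collection-assigned keyword, each found as a MeSH descriptor, a MeSH entry
term, or a token phrase in title or abstract — and *high quality* — it was
abstracted by an evidence-based synoptic journal or published with an
accompanying editorial.  Both conditions must hold; a strategy gets no
credit for a high-quality article on the wrong topic.

Keyword matching uses the same case-insensitive token-phrase rule as
retrieval, applied to the ORIGINAL (pre-normalization) keywords; keywords
containing commas are additionally tried in inverted form, since both
surface forms denote the same heading.

None of the quality metadata consulted here is visible to the search
strategies (see the incorporation-bias guard test).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .corpus_model import CitationRecord, ClinicalQuestion, CorpusError
from .query_builder import invert_comma_term
from .retrieval_index import _RecordView, match_term

#: Evidence-based synoptic journals whose abstraction marks an article high quality.
DEFAULT_SYNOPTIC_JOURNALS = frozenset({
    "ACP Journal Club",
    "InfoPoems",
    "Evidence Based Dentistry",
    "Evidence Based Medicine",
    "Evidence Based Nursing",
    "Evidence Based Mental Health",
})


@dataclass(frozen=True)
class QualityConfig:
    """Which signals count as high quality."""

    synoptic_journals: frozenset[str] = DEFAULT_SYNOPTIC_JOURNALS
    editorial_counts: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "synoptic_journals", frozenset(self.synoptic_journals))
        if not self.synoptic_journals and not self.editorial_counts:
            raise CorpusError("at least one quality criterion must be enabled")


def is_relevant(record: CitationRecord, question: ClinicalQuestion) -> bool:
    """Every assigned keyword present as MeSH descriptor/entry term or text phrase."""
    view = _RecordView(record)
    for keyword in question.keywords:
        forms = {keyword}
        if "," in keyword:
            forms.add(invert_comma_term(keyword))
        if not any(match_term(view, form) for form in forms):
            return False
    return True


def is_high_quality(record: CitationRecord,
                    config: QualityConfig = QualityConfig()) -> bool:
    """Synoptic-journal abstraction or an accompanying editorial."""
    if record.synoptic_reviews & config.synoptic_journals:
        return True
    return config.editorial_counts and record.has_editorial


def qualifying_set(records: Iterable[CitationRecord], question: ClinicalQuestion,
                   config: QualityConfig = QualityConfig()) -> set[int]:
    """PMIDs of records that are both relevant and high quality."""
    return {
        rec.pmid for rec in records
        if is_relevant(rec, question) and is_high_quality(rec, config)
    }
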