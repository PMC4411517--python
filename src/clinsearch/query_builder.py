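"""Turn a question's keywords into Boolean and web-search query strings.

Collection keywords are MeSH-style headings whose inverted comma form
("Anemia, Sickle Cell") reads poorly as a text word, so two normalization
rules are applied before querying, in fixed order:

1. comma inversion — "Anemia, Sickle Cell" becomes "Sickle Cell Anemia"
   (multi-comma headings reverse all segments: "X, Y, Z" -> "Z Y X");
2. vocabulary substitution — the whole word "neoplasms" becomes "cancer",
   case-insensitively, because lay and full-text sources say "cancer".

Normalized terms are joined with "AND" for the Boolean strategies, or with
spaces plus the literal suffix ``PMID ~random ~trial`` for the web strategy
(the tilde being the historical Google synonym operator).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .corpus_model import ClinicalQuestion, CorpusError

WEB_QUERY_SUFFIX = "PMID ~random ~trial"

_NEOPLASMS_RE = re.compile(r"\bneoplasms\b", re.IGNORECASE)
_WS_RE = re.compile(r"\s+")


@dataclass(frozen=True)
class BaseQuery:
    """An ordered conjunction of normalized search terms (no field tags)."""

    terms: tuple[str, ...]
    connector: str = "AND"

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        if not self.terms:
            raise CorpusError("base query needs at least one term")
        if any("," in t for t in self.terms):
            raise CorpusError("base query terms must be comma-free after normalization")

    def render(self) -> str:
        return f" {self.connector} ".join(self.terms)


def invert_comma_term(term: str) -> str:
    """Invert a comma-separated heading so it works as a text word.

    "anemia, sickle cell" -> "sickle cell anemia"; comma-free terms are
    returned unchanged (idempotent).
    """
    if "," not in term:
        return term
    segments = [s.strip() for s in term.split(",") if s.strip()]
    return " ".join(reversed(segments))


def substitute_neoplasms(term: str) -> str:
    """Replace each whole-word "neoplasms" with "cancer" (case-insensitive)."""
    return _NEOPLASMS_RE.sub("cancer", term)


def normalize_term(term: str) -> str:
    """Apply the full normalization pipeline: inversion, then substitution."""
    return _WS_RE.sub(" ", substitute_neoplasms(invert_comma_term(term))).strip()


def build_base_query(question: ClinicalQuestion) -> BaseQuery:
    """Normalize every keyword (order preserved) into the Boolean base query."""
    if not question.keywords:
        raise CorpusError(f"question {question.question_id!r} has no keywords")
    return BaseQuery(terms=tuple(normalize_term(k) for k in question.keywords))


def build_web_query(question: ClinicalQuestion) -> str:
    """Render the Google/Scholar query: normalized terms plus the PMID/trial suffix."""
    base = build_base_query(question)
    return " ".join([*base.terms, WEB_QUERY_SUFFIX])
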