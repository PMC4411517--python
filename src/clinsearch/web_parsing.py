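"""Extract article identifiers from saved web-search result pages.

The web strategies (Google / Google Scholar) do not return bibliographic
records; instead, every result entry's visible text and hyperlink URLs are
scanned for PubMed identifiers and DOIs, which are then resolved against a
local citation lookup.  Live page fetching is out of scope — result pages
arrive as saved HTML or plain-text files.

Recognition rules (stated here because they are a design choice, not a
published standard):

* PMID: a digit run of length 7-8 either inside a PubMed URL
  (``.../pubmed/<digits>`` or ``pubmed.ncbi.nlm.nih.gov/<digits>``) or
  adjacent to the case-insensitive marker "PMID".  Bare digit runs elsewhere
  are ignored to avoid matching years and phone numbers.
* DOI: the usual ``10.<registrant>/<suffix>`` pattern, trailing punctuation
  trimmed.

In HTML documents each anchor element is one result entry; in plain text
each non-empty line is one entry.  ``max_results`` caps the number of result
*entries* scanned (mirroring a 50-results-per-page search), not the number
of identifiers found.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from lxml import html as lxml_html

from .corpus_model import CitationRecord, CorpusError

logger = logging.getLogger(__name__)

_PUBMED_URL_RE = re.compile(
    r"(?:/pubmed/|pubmed\.ncbi\.nlm\.nih\.gov/)(\d{7,8})(?!\d)", re.IGNORECASE
)
_PMID_MARKER_RE = re.compile(r"\bPMID\b[:\s/-]*(\d{7,8})(?!\d)", re.IGNORECASE)
_DOI_RE = re.compile(r"\b(10\.\d{4,9}/[^\s\"'<>)\]]+)")


@dataclass(frozen=True)
class IdentifierHit:
    """One identifier found on a result page, with its entry rank (1-based)."""

    kind: str  # "pmid" | "doi"
    value: str
    source_rank: int

    def __post_init__(self) -> None:
        if self.kind not in ("pmid", "doi"):
            raise CorpusError(f"identifier kind must be pmid|doi, got {self.kind!r}")
        if self.kind == "pmid" and not re.fullmatch(r"\d{7,8}", self.value):
            raise CorpusError(f"bad PMID value {self.value!r}")
        if self.kind == "doi" and not re.match(r"10\.\d+/", self.value):
            raise CorpusError(f"bad DOI value {self.value!r}")
        if self.source_rank < 1:
            raise CorpusError("source_rank is 1-based")


def _strip_doi(doi: str) -> str:
    return doi.rstrip(".,;")


def _scan_fragment(text: str) -> list[tuple[str, str]]:
    """All (kind, value) identifier occurrences in one text fragment, in order."""
    found: list[tuple[int, str, str]] = []
    for m in _PUBMED_URL_RE.finditer(text):
        found.append((m.start(1), "pmid", m.group(1)))
    for m in _PMID_MARKER_RE.finditer(text):
        found.append((m.start(1), "pmid", m.group(1)))
    for m in _DOI_RE.finditer(text):
        found.append((m.start(1), "doi", _strip_doi(m.group(1))))
    found.sort(key=lambda t: t[0])
    return [(kind, value) for _, kind, value in found]


def _entries_from_html(document: str) -> list[str]:
    """One fragment per result entry: each anchor's href, text and trailing
    snippet (the tail text up to the next element)."""
    tree = lxml_html.fromstring(document)
    entries = []
    for a in tree.iter("a"):
        href = a.get("href", "")
        entries.append(f"{href} {a.text_content()} {a.tail or ''}")
    return entries


def _entries_from_text(document: str) -> list[str]:
    return [line for line in document.splitlines() if line.strip()]


def extract_identifiers(document: str, max_results: int = 50) -> list[IdentifierHit]:
    """Scan the first ``max_results`` result entries for PMIDs and DOIs.

    Returns hits ordered by first appearance, deduplicated on (kind, value)
    with the earliest rank kept.  An empty document yields an empty list.
    """
    if not document.strip():
        return []
    looks_like_html = bool(re.search(r"<a\s", document, re.IGNORECASE))
    entries = _entries_from_html(document) if looks_like_html else _entries_from_text(document)
    hits: list[IdentifierHit] = []
    seen: set[tuple[str, str]] = set()
    for rank, fragment in enumerate(entries[:max_results], start=1):
        for kind, value in _scan_fragment(fragment):
            key = (kind, value)
            if key not in seen:
                seen.add(key)
                hits.append(IdentifierHit(kind=kind, value=value, source_rank=rank))
    return hits


class CorpusLookup:
    """PMID/DOI -> record resolution over a local corpus."""

    def __init__(self, corpus: Iterable[CitationRecord]) -> None:
        self.by_pmid: dict[int, CitationRecord] = {}
        self.by_doi: dict[str, CitationRecord] = {}
        for rec in corpus:
            self.by_pmid[rec.pmid] = rec
            if rec.doi:
                self.by_doi[rec.doi.lower()] = rec

    def resolve(self, hit: IdentifierHit) -> CitationRecord | None:
        if hit.kind == "pmid":
            return self.by_pmid.get(int(hit.value))
        return self.by_doi.get(hit.value.lower())


def resolve_to_records(hits: Sequence[IdentifierHit],
                       lookup: CorpusLookup) -> list[CitationRecord]:
    """Resolve hits in order to citation records, deduplicated by PMID.

    Unresolvable identifiers are dropped; their count is logged.
    """
    records: list[CitationRecord] = []
    seen_pmids: set[int] = set()
    dropped = 0
    for hit in hits:
        rec = lookup.resolve(hit)
        if rec is None:
            dropped += 1
            continue
        if rec.pmid not in seen_pmids:
            seen_pmids.add(rec.pmid)
            records.append(rec)
    if dropped:
        logger.info("dropped %d unresolvable identifier hit(s)", dropped)
    return records
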