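"""Domain types for MEDLINE-like citations and clinical questions, with readers
and writers for the corpus and question interchange formats.

The canonical interchange format is JSONL (one citation object per line).  Two
additional dialects are supported for interoperability with bibliographic
tooling: a PubMed-XML subset and a MEDLINE ``.nbib`` subset.  Both parse only
the fields of :class:`CitationRecord` and ignore everything else; both carry
the fields the real schemas lack (MeSH entry terms, synoptic-journal reviews,
the accompanying-editorial flag) in documented dialect extensions so that
write-then-read is the identity for every format.

Questions are read from CSV with header ``question_id,keywords`` (keywords
pipe-separated, order significant) or from a JSON array of objects.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Medline
from lxml import etree


class CorpusError(ValueError):
    """Raised for malformed or invariant-violating corpus/question input."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeshAssignment:
    """One MeSH heading assigned to a citation.

    ``descriptor`` is the controlled heading (e.g. "Thyroid Neoplasms");
    ``entry_terms`` are its synonyms (e.g. "thyroid cancer"); ``is_major``
    marks the heading as a central topic of the article; ``subheadings`` are
    qualifiers such as "therapeutic use".
    """

    descriptor: str
    entry_terms: frozenset[str] = frozenset()
    is_major: bool = False
    subheadings: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.descriptor or not self.descriptor.strip():
            raise CorpusError("MeSH descriptor must be non-empty")
        object.__setattr__(self, "entry_terms", frozenset(self.entry_terms))
        object.__setattr__(self, "subheadings", frozenset(self.subheadings))
        if self.descriptor in self.entry_terms:
            raise CorpusError(
                f"entry terms of {self.descriptor!r} must not repeat the descriptor"
            )


@dataclass(frozen=True)
class CitationRecord:
    """One MEDLINE-like citation with the metadata the pipeline consumes."""

    pmid: int
    title: str
    journal: str
    pub_date: _dt.date
    doi: str | None = None
    abstract: str | None = None
    mesh_terms: tuple[MeshAssignment, ...] = ()
    pub_types: frozenset[str] = frozenset()
    synoptic_reviews: frozenset[str] = frozenset()
    has_editorial: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.pmid, int) or self.pmid <= 0:
            raise CorpusError(f"pmid must be a positive integer, got {self.pmid!r}")
        object.__setattr__(self, "mesh_terms", tuple(self.mesh_terms))
        object.__setattr__(self, "pub_types", frozenset(self.pub_types))
        object.__setattr__(self, "synoptic_reviews", frozenset(self.synoptic_reviews))


@dataclass(frozen=True)
class ClinicalQuestion:
    """A clinical question represented by its assigned keyword list.

    Keywords are the collection-assigned (pre-normalization) surface forms,
    typically MeSH headings, possibly containing commas ("Anemia, Sickle
    Cell"); their order is preserved.
    """

    question_id: str
    keywords: tuple[str, ...]
    category: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "keywords", tuple(self.keywords))
        if not self.keywords:
            raise CorpusError(f"question {self.question_id!r} has no keywords")
        if any(not k or not k.strip() for k in self.keywords):
            raise CorpusError(f"question {self.question_id!r} has a blank keyword")


# ---------------------------------------------------------------------------
# JSONL dialect
# ---------------------------------------------------------------------------

def record_to_dict(record: CitationRecord) -> dict:
    """Serialize a record to the JSONL field layout (sets sorted for determinism)."""
    return {
        "pmid": record.pmid,
        "doi": record.doi,
        "title": record.title,
        "abstract": record.abstract,
        "journal": record.journal,
        "pub_date": record.pub_date.isoformat(),
        "mesh_terms": [
            {
                "descriptor": m.descriptor,
                "entry_terms": sorted(m.entry_terms),
                "is_major": m.is_major,
                "subheadings": sorted(m.subheadings),
            }
            for m in record.mesh_terms
        ],
        "pub_types": sorted(record.pub_types),
        "synoptic_reviews": sorted(record.synoptic_reviews),
        "has_editorial": record.has_editorial,
    }


def record_from_dict(obj: dict) -> CitationRecord:
    if "pmid" not in obj or obj["pmid"] is None:
        raise CorpusError("citation record missing pmid")
    try:
        pub_date = _dt.date.fromisoformat(obj["pub_date"])
    except (KeyError, TypeError, ValueError) as exc:
        raise CorpusError(f"record {obj.get('pmid')}: bad pub_date") from exc
    return CitationRecord(
        pmid=int(obj["pmid"]),
        doi=obj.get("doi"),
        title=obj.get("title", ""),
        abstract=obj.get("abstract"),
        journal=obj.get("journal", ""),
        pub_date=pub_date,
        mesh_terms=tuple(
            MeshAssignment(
                descriptor=m["descriptor"],
                entry_terms=frozenset(m.get("entry_terms", ())),
                is_major=bool(m.get("is_major", False)),
                subheadings=frozenset(m.get("subheadings", ())),
            )
            for m in obj.get("mesh_terms", ())
        ),
        pub_types=frozenset(obj.get("pub_types", ())),
        synoptic_reviews=frozenset(obj.get("synoptic_reviews", ())),
        has_editorial=bool(obj.get("has_editorial", False)),
    )


def _check_unique_pmids(records: Sequence[CitationRecord]) -> None:
    seen: set[int] = set()
    for rec in records:
        if rec.pmid in seen:
            raise CorpusError(f"duplicate PMID {rec.pmid} in corpus")
        seen.add(rec.pmid)


def _read_jsonl(path: Path) -> list[CitationRecord]:
    records: list[CitationRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: malformed JSON") from exc
            try:
                records.append(record_from_dict(obj))
            except CorpusError as exc:
                raise CorpusError(f"{path}:{lineno}: {exc}") from exc
    return records


def _write_jsonl(records: Iterable[CitationRecord], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(record_to_dict(rec), ensure_ascii=False) + "\n")


# ---------------------------------------------------------------------------
# MEDLINE .nbib dialect
#
# Standard tags: PMID, TI, AB, JT, DP, PT, MH (leading "*" = major topic,
# "/qualifier" = subheading), AID with "[doi]".  Dialect extensions: ZET
# (entry terms, "descriptor|term|term..."), ZSY (synoptic journal), ZED
# (editorial flag, "1").
# ---------------------------------------------------------------------------

_MONTHS = {m: i + 1 for i, m in enumerate(
    ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
     "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"])}


def _parse_dp(value: str) -> _dt.date:
    """Parse a MEDLINE DP field; missing day/month completed as 1/Jan."""
    parts = value.split()
    year = int(parts[0])
    month = _MONTHS.get(parts[1][:3], 1) if len(parts) > 1 else 1
    day = int(parts[2]) if len(parts) > 2 else 1
    return _dt.date(year, month, day)


def _read_nbib(path: Path) -> list[CitationRecord]:
    records: list[CitationRecord] = []
    with open(path, encoding="utf-8") as fh:
        for idx, raw in enumerate(Medline.parse(fh), 1):
            if not raw:
                continue
            if "PMID" not in raw:
                raise CorpusError(f"{path}: record {idx} missing PMID")
            entry_terms: dict[str, frozenset[str]] = {}
            for zet in raw.get("ZET", ()):
                descr, *terms = zet.split("|")
                entry_terms[descr] = frozenset(t for t in terms if t)
            mesh = []
            for mh in raw.get("MH", ()):
                is_major = mh.startswith("*")
                descr, *quals = mh.lstrip("*").split("/")
                mesh.append(MeshAssignment(
                    descriptor=descr,
                    entry_terms=entry_terms.get(descr, frozenset()),
                    is_major=is_major,
                    subheadings=frozenset(quals),
                ))
            doi = None
            for aid in raw.get("AID", ()):
                if aid.endswith("[doi]"):
                    doi = aid[: -len("[doi]")].strip()
            try:
                records.append(CitationRecord(
                    pmid=int(raw["PMID"]),
                    title=raw.get("TI", ""),
                    abstract=raw.get("AB") or None,
                    journal=raw.get("JT", ""),
                    pub_date=_parse_dp(raw["DP"]),
                    doi=doi,
                    mesh_terms=tuple(mesh),
                    pub_types=frozenset(raw.get("PT", ())),
                    synoptic_reviews=frozenset(raw.get("ZSY", ())),
                    has_editorial=bool(raw.get("ZED")),
                ))
            except (KeyError, ValueError) as exc:
                raise CorpusError(f"{path}: record {idx}: {exc}") from exc
    return records


_MONTH_NAMES = {v: k for k, v in _MONTHS.items()}


def _write_nbib(records: Iterable[CitationRecord], path: Path) -> None:
    def clean(text: str) -> str:
        # values are written on one line; the reader does not rejoin wraps
        return re.sub(r"\s+", " ", text).strip()

    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            lines = [f"PMID- {rec.pmid}"]
            dp = f"{rec.pub_date.year} {_MONTH_NAMES[rec.pub_date.month]} {rec.pub_date.day}"
            lines.append(f"DP  - {dp}")
            lines.append(f"TI  - {clean(rec.title)}")
            if rec.abstract:
                lines.append(f"AB  - {clean(rec.abstract)}")
            lines.append(f"JT  - {clean(rec.journal)}")
            for pt in sorted(rec.pub_types):
                lines.append(f"PT  - {pt}")
            for m in rec.mesh_terms:
                star = "*" if m.is_major else ""
                quals = "".join(f"/{q}" for q in sorted(m.subheadings))
                lines.append(f"MH  - {star}{m.descriptor}{quals}")
                if m.entry_terms:
                    lines.append(
                        "ZET - " + "|".join([m.descriptor, *sorted(m.entry_terms)])
                    )
            if rec.doi:
                lines.append(f"AID - {rec.doi} [doi]")
            for name in sorted(rec.synoptic_reviews):
                lines.append(f"ZSY - {name}")
            if rec.has_editorial:
                lines.append("ZED - 1")
            fh.write("\n".join(lines) + "\n\n")


# ---------------------------------------------------------------------------
# PubMed-XML dialect (subset)
# ---------------------------------------------------------------------------

def _read_pubmed_xml(path: Path) -> list[CitationRecord]:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusError(f"{path}: malformed XML: {exc}") from exc
    records: list[CitationRecord] = []
    for idx, art in enumerate(tree.iter("PubmedArticle"), 1):
        pmid_el = art.find(".//PMID")
        if pmid_el is None or not (pmid_el.text or "").strip():
            raise CorpusError(f"{path}: PubmedArticle {idx} missing PMID")
        date_el = art.find(".//PubDate")
        year = int(date_el.findtext("Year", "1900")) if date_el is not None else 1900
        month = _MONTHS.get(date_el.findtext("Month", "Jan")[:3], 1) if date_el is not None else 1
        day = int(date_el.findtext("Day", "1")) if date_el is not None else 1
        mesh = []
        for mh in art.iter("MeshHeading"):
            d = mh.find("DescriptorName")
            if d is None or not (d.text or "").strip():
                raise CorpusError(f"{path}: PubmedArticle {idx}: empty MeSH descriptor")
            mesh.append(MeshAssignment(
                descriptor=d.text,
                is_major=d.get("MajorTopicYN", "N") == "Y",
                subheadings=frozenset(q.text for q in mh.iter("QualifierName") if q.text),
                entry_terms=frozenset(t.text for t in mh.iter("EntryTerm") if t.text),
            ))
        doi = None
        for aid in art.iter("ArticleId"):
            if aid.get("IdType") == "doi" and aid.text:
                doi = aid.text
        try:
            records.append(CitationRecord(
                pmid=int(pmid_el.text),
                title=art.findtext(".//ArticleTitle", ""),
                abstract=art.findtext(".//AbstractText") or None,
                journal=art.findtext(".//Journal/Title", ""),
                pub_date=_dt.date(year, month, day),
                doi=doi,
                mesh_terms=tuple(mesh),
                pub_types=frozenset(
                    pt.text for pt in art.iter("PublicationType") if pt.text
                ),
                synoptic_reviews=frozenset(
                    s.text for s in art.iter("SynopticReview") if s.text
                ),
                has_editorial=art.findtext(".//HasEditorial", "N") == "Y",
            ))
        except (ValueError, TypeError) as exc:
            raise CorpusError(f"{path}: PubmedArticle {idx}: {exc}") from exc
    return records


def _write_pubmed_xml(records: Iterable[CitationRecord], path: Path) -> None:
    root = etree.Element("PubmedArticleSet")
    for rec in records:
        art = etree.SubElement(root, "PubmedArticle")
        cit = etree.SubElement(art, "MedlineCitation")
        etree.SubElement(cit, "PMID").text = str(rec.pmid)
        article = etree.SubElement(cit, "Article")
        journal = etree.SubElement(article, "Journal")
        etree.SubElement(journal, "Title").text = rec.journal
        pubdate = etree.SubElement(etree.SubElement(journal, "JournalIssue"), "PubDate")
        etree.SubElement(pubdate, "Year").text = str(rec.pub_date.year)
        etree.SubElement(pubdate, "Month").text = _MONTH_NAMES[rec.pub_date.month]
        etree.SubElement(pubdate, "Day").text = str(rec.pub_date.day)
        etree.SubElement(article, "ArticleTitle").text = rec.title
        if rec.abstract:
            abstract = etree.SubElement(article, "Abstract")
            etree.SubElement(abstract, "AbstractText").text = rec.abstract
        ptl = etree.SubElement(article, "PublicationTypeList")
        for pt in sorted(rec.pub_types):
            etree.SubElement(ptl, "PublicationType").text = pt
        mhl = etree.SubElement(cit, "MeshHeadingList")
        for m in rec.mesh_terms:
            mh = etree.SubElement(mhl, "MeshHeading")
            d = etree.SubElement(mh, "DescriptorName")
            d.text = m.descriptor
            d.set("MajorTopicYN", "Y" if m.is_major else "N")
            for q in sorted(m.subheadings):
                etree.SubElement(mh, "QualifierName").text = q
            if m.entry_terms:
                etl = etree.SubElement(mh, "EntryTermList")
                for t in sorted(m.entry_terms):
                    etree.SubElement(etl, "EntryTerm").text = t
        # dialect extensions for the reference-standard fields
        if rec.synoptic_reviews:
            srl = etree.SubElement(cit, "SynopticReviewList")
            for s in sorted(rec.synoptic_reviews):
                etree.SubElement(srl, "SynopticReview").text = s
        etree.SubElement(cit, "HasEditorial").text = "Y" if rec.has_editorial else "N"
        pubmed_data = etree.SubElement(art, "PubmedData")
        idl = etree.SubElement(pubmed_data, "ArticleIdList")
        pmid_id = etree.SubElement(idl, "ArticleId")
        pmid_id.set("IdType", "pubmed")
        pmid_id.text = str(rec.pmid)
        if rec.doi:
            doi_id = etree.SubElement(idl, "ArticleId")
            doi_id.set("IdType", "doi")
            doi_id.text = rec.doi
    etree.ElementTree(root).write(
        str(path), pretty_print=True, xml_declaration=True, encoding="UTF-8"
    )


# ---------------------------------------------------------------------------
# Public read/write API
# ---------------------------------------------------------------------------

_READERS = {"jsonl": _read_jsonl, "pubmed_xml": _read_pubmed_xml, "medline_nbib": _read_nbib}
_WRITERS = {"jsonl": _write_jsonl, "pubmed_xml": _write_pubmed_xml, "medline_nbib": _write_nbib}

CORPUS_FORMATS = tuple(_READERS)


def read_corpus(path: str | Path, format: str = "jsonl") -> list[CitationRecord]:
    """Read a citation corpus, preserving file order and enforcing PMID uniqueness."""
    if format not in _READERS:
        raise CorpusError(f"unknown corpus format {format!r}; expected one of {CORPUS_FORMATS}")
    records = _READERS[format](Path(path))
    _check_unique_pmids(records)
    return records


def write_corpus(records: Sequence[CitationRecord], path: str | Path,
                 format: str = "jsonl") -> None:
    """Write a corpus in the named dialect; inverse of :func:`read_corpus`."""
    if format not in _WRITERS:
        raise CorpusError(f"unknown corpus format {format!r}; expected one of {CORPUS_FORMATS}")
    _check_unique_pmids(list(records))
    _WRITERS[format](records, Path(path))


def read_questions(path: str | Path) -> list[ClinicalQuestion]:
    """Read clinical questions from CSV (``question_id,keywords``) or a JSON array."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        return []
    questions: list[ClinicalQuestion] = []
    if text.lstrip().startswith("["):
        for idx, obj in enumerate(json.loads(text), 1):
            try:
                questions.append(ClinicalQuestion(
                    question_id=str(obj["question_id"]),
                    keywords=tuple(obj["keywords"]),
                    category=obj.get("category"),
                ))
            except (KeyError, CorpusError) as exc:
                raise CorpusError(f"{path}: question {idx}: {exc}") from exc
        return questions
    reader = csv.DictReader(io.StringIO(text))
    if reader.fieldnames is None or "question_id" not in reader.fieldnames \
            or "keywords" not in reader.fieldnames:
        raise CorpusError(f"{path}: expected CSV header with question_id,keywords")
    for lineno, row in enumerate(reader, 2):
        keywords = tuple(k.strip() for k in (row["keywords"] or "").split("|"))
        try:
            questions.append(ClinicalQuestion(
                question_id=row["question_id"],
                keywords=keywords,
                category=(row.get("category") or None),
            ))
        except CorpusError as exc:
            raise CorpusError(f"{path}:{lineno}: {exc}") from exc
    return questions


def write_questions(questions: Sequence[ClinicalQuestion], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["question_id", "keywords", "category"])
        for q in questions:
            writer.writerow([q.question_id, "|".join(q.keywords), q.category or ""])
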