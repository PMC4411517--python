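"""Synthetic MEDLINE-like corpora, question sets and web-result fixtures.

Every stage of the pipeline — Boolean retrieval, the iterative strategy, web
identifier parsing and the reference standard — can be exercised offline
against material produced here.  The generator emulates the *statistical
shape* the method assumes, not natural language: titles and abstracts are
bags of vocabulary surface forms plus filler tokens, publication types and
quality flags are Bernoulli draws, and dates are uniform over the configured
range.

Questions mirror the keyword structure of an indexed clinical-questions
collection: a median of two MeSH-style keywords per question, a configurable
fraction carrying commas ("Anemia, Sickle Cell") or the word "neoplasms" to
exercise query normalization.

``plant_answers`` makes end-to-end precision analytically forced: planted
records receive the most recent dates (the head of the date-descending
ranking) and attributes that pass every iteration filter up to a chosen
stopping level, so the iterative strategy's first-k results contain exactly
the requested number of qualifying citations.

All generators draw from named substreams split from the master seed, so
adding one generator never perturbs another.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .corpus_model import CitationRecord, ClinicalQuestion, CorpusError, MeshAssignment
from .query_builder import normalize_term
from .reference_standard import (
    DEFAULT_SYNOPTIC_JOURNALS,
    QualityConfig,
    is_high_quality,
    is_relevant,
)
from .retrieval_index import tokenize

# MeSH-style vocabulary: (descriptor, entry terms).  Includes comma-inverted
# and "neoplasms" headings so normalization paths are exercised.
DEFAULT_VOCABULARY: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("Hypertension", ("high blood pressure",)),
    ("Hyperlipidemias", ("hyperlipidemia",)),
    ("Urinary Tract Infections", ("urinary infection",)),
    ("Thyroid Neoplasms", ("thyroid cancer",)),
    ("Breast Neoplasms", ("breast cancer",)),
    ("Colonic Neoplasms", ("colon cancer",)),
    ("Prostatic Neoplasms", ("prostate cancer",)),
    ("Anemia, Sickle Cell", ("sickle cell anemia",)),
    ("Diabetes Mellitus, Type 2", ("type 2 diabetes",)),
    ("Pulmonary Disease, Chronic Obstructive", ("copd",)),
    ("Radiation Injuries", ()),
    ("Asthma", ()),
    ("Myocardial Infarction", ("heart attack",)),
    ("Hydroxyurea", ()),
    ("Bronchiectasis", ()),
    ("Atrial Fibrillation", ()),
    ("Heart Failure", ("cardiac failure",)),
    ("Osteoporosis", ()),
    ("Pneumonia", ()),
    ("Migraine Disorders", ("migraine",)),
    ("Depressive Disorder", ("depression",)),
    ("Pulmonary Embolism", ()),
    ("Stroke", ()),
    ("Gout", ()),
    ("Anticoagulants", ()),
    ("Metformin", ()),
    ("Osteoarthritis", ()),
    ("Peptic Ulcer", ()),
    ("Warfarin", ()),
    ("Acetylcysteine", ()),
)

#: Pool of journal titles; the first CORE_JOURNAL_COUNT form the "core"
#: sublist standing in for the 106-journal core clinical list.
DEFAULT_JOURNAL_POOL: tuple[str, ...] = (
    "The Lancet",
    "JAMA",
    "New England Journal of Medicine",
    "BMJ",
    "Annals of Internal Medicine",
    "Circulation",
    "Chest",
    "Archives of Internal Medicine",
    "Medical Hypotheses",
    "Journal of Investigative Practice",
    "Clinical Case Notes",
    "Regional Health Review",
    "Cochrane Database of Systematic Reviews",
    "International Archive of Specialty Medicine",
)
CORE_JOURNAL_COUNT = 8

_FILLER = ("management", "outcomes", "patients", "therapy", "assessment",
           "follow", "up", "cohort", "evaluation", "practice", "care",
           "adults", "effects", "clinical", "hospital", "community")

#: Background (non-planted) records carry a quality flag at this rate.
BACKGROUND_QUALITY_RATE = 0.05

# named substreams split from the master seed
_STREAM_CORPUS, _STREAM_QUESTIONS, _STREAM_PLANT, _STREAM_WEB = 11, 23, 37, 53


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([stream, seed]))


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study conditions.

    The defaults mirror the study layout this package models: 312 treatment
    questions with a median of 2 keywords each, a futility point of k = 50,
    a core-journal sublist, and MEDLINE-plausible rates of trial publication
    types and abstracts.  The corpus size (2,000 citations) is a desk-scale
    stand-in for MEDLINE.
    """

    n_citations: int = 2000
    n_questions: int = 312
    vocabulary: tuple[tuple[str, tuple[str, ...]], ...] = DEFAULT_VOCABULARY
    p_rct_pubtype: float = 0.15
    p_sysrev: float = 0.05
    p_abstract: float = 0.8
    p_synoptic_given_quality: float = 0.5
    journal_pool: tuple[str, ...] = DEFAULT_JOURNAL_POOL
    n_core_journals: int = CORE_JOURNAL_COUNT
    keywords_per_question: tuple[tuple[int, float], ...] = ((1, 0.25), (2, 0.5), (3, 0.25))
    p_comma_keyword: float = 0.2
    p_neoplasms_keyword: float = 0.2
    date_range: tuple[_dt.date, _dt.date] = (_dt.date(2000, 1, 1), _dt.date(2009, 12, 31))
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_rct_pubtype", "p_sysrev", "p_abstract",
                     "p_synoptic_given_quality", "p_comma_keyword",
                     "p_neoplasms_keyword"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise CorpusError(f"{name} must be in [0, 1], got {p}")
        if self.n_citations < 1:
            raise CorpusError("n_citations must be >= 1")
        if not self.vocabulary:
            raise CorpusError("vocabulary must be non-empty")
        if not 1 <= self.n_core_journals <= len(self.journal_pool):
            raise CorpusError("core journal sublist must be within journal_pool")
        if self.date_range[0] > self.date_range[1]:
            raise CorpusError("date_range start must not exceed end")

    @property
    def core_journals(self) -> tuple[str, ...]:
        return self.journal_pool[: self.n_core_journals]


@dataclass(frozen=True)
class PlantSpec:
    """How many qualifying / near-miss citations to guarantee for a question."""

    question_id: str
    n_qualifying_in_topk: int = 0
    n_relevant_lowq: int = 0
    n_highq_irrelevant: int = 0

    def __post_init__(self) -> None:
        if min(self.n_qualifying_in_topk, self.n_relevant_lowq,
               self.n_highq_irrelevant) < 0:
            raise CorpusError("plant counts must be >= 0")


# ---------------------------------------------------------------------------
# Corpus generation
# ---------------------------------------------------------------------------

def _choice(rng: np.random.Generator, items: Sequence, size: int | None = None,
            replace_: bool = True):
    idx = rng.choice(len(items), size=size, replace=replace_)
    if size is None:
        return items[int(idx)]
    return [items[int(i)] for i in idx]


def generate_corpus(config: SimulationConfig) -> list[CitationRecord]:
    """Draw ``n_citations`` records; identical config (incl. seed) => identical output."""
    rng = _rng(config.seed, _STREAM_CORPUS)
    start, end = config.date_range
    span = (end - start).days + 1
    synoptic_pool = sorted(DEFAULT_SYNOPTIC_JOURNALS)
    records: list[CitationRecord] = []
    for i in range(config.n_citations):
        n_topics = int(rng.integers(1, 4))
        topic_idx = rng.choice(len(config.vocabulary), size=n_topics, replace=False)
        topics = [config.vocabulary[int(t)] for t in topic_idx]
        surfaces = [
            (descr if not entries or rng.random() < 0.5 else _choice(rng, entries))
            for descr, entries in topics
        ]

        pub_types = {"Journal Article"}
        is_rct = rng.random() < config.p_rct_pubtype
        if is_rct:
            pub_types.add("Randomized Controlled Trial")
        if rng.random() < config.p_sysrev:
            pub_types.add("Meta-Analysis")
        if not is_rct and "Meta-Analysis" not in pub_types and rng.random() < 0.15:
            pub_types.add(str(_choice(rng, ("Review", "Letter", "Editorial"))))

        filler = _choice(rng, _FILLER, size=3)
        title = f"{filler[0].capitalize()} of {' and '.join(surfaces)} in {filler[1]}"
        if is_rct and rng.random() < 0.7:
            title += ": a randomized controlled trial"
        elif "Meta-Analysis" in pub_types and rng.random() < 0.7:
            title += ": a systematic review"

        abstract = None
        if rng.random() < config.p_abstract:
            abstract = (f"We studied {' and '.join(surfaces)} among {filler[2]} "
                        f"{_choice(rng, _FILLER)}.")
            if is_rct:
                abstract += " Participants were randomized."

        major_flags = [bool(rng.random() < 0.5) for _ in topics]
        if not any(major_flags):  # MEDLINE records carry >= 1 major topic
            major_flags[0] = True
        mesh = []
        for (descr, entries), is_major in zip(topics, major_flags):
            subheadings = set()
            if rng.random() < 0.2:
                subheadings.add("therapeutic use")
            if rng.random() < 0.2:
                subheadings.add("drug therapy")
            mesh.append(MeshAssignment(
                descriptor=descr,
                entry_terms=frozenset(entries),
                is_major=is_major,
                subheadings=frozenset(subheadings),
            ))

        synoptic: frozenset[str] = frozenset()
        has_editorial = False
        if rng.random() < BACKGROUND_QUALITY_RATE:
            if rng.random() < config.p_synoptic_given_quality:
                synoptic = frozenset({str(_choice(rng, synoptic_pool))})
            else:
                has_editorial = True

        pmid = 10_000_000 + i
        records.append(CitationRecord(
            pmid=pmid,
            doi=(f"10.5555/syn.{pmid}" if rng.random() < 0.6 else None),
            title=title,
            abstract=abstract,
            journal=str(_choice(rng, config.journal_pool)),
            pub_date=start + _dt.timedelta(days=int(rng.integers(span))),
            mesh_terms=tuple(mesh),
            pub_types=frozenset(pub_types),
            synoptic_reviews=synoptic,
            has_editorial=has_editorial,
        ))
    return records


# ---------------------------------------------------------------------------
# Question generation
# ---------------------------------------------------------------------------

def generate_questions(config: SimulationConfig) -> list[ClinicalQuestion]:
    """Draw ``n_questions`` keyword lists from the vocabulary."""
    rng = _rng(config.seed, _STREAM_QUESTIONS)
    descriptors = [d for d, _ in config.vocabulary]
    comma_descr = [d for d in descriptors if "," in d]
    neo_descr = [d for d in descriptors if "neoplasms" in d.lower()]
    counts = [k for k, _ in config.keywords_per_question]
    weights = np.array([w for _, w in config.keywords_per_question], dtype=float)
    weights = weights / weights.sum()
    questions = []
    for i in range(config.n_questions):
        n_kw = int(rng.choice(counts, p=weights))
        forced: list[str] = []
        if comma_descr and rng.random() < config.p_comma_keyword:
            forced.append(str(_choice(rng, comma_descr)))
        if neo_descr and rng.random() < config.p_neoplasms_keyword:
            forced.append(str(_choice(rng, neo_descr)))
        forced = forced[:n_kw]
        remaining = [d for d in descriptors if d not in forced]
        extra = _choice(rng, remaining, size=n_kw - len(forced), replace_=False)
        keywords = forced + [str(e) for e in extra]
        questions.append(ClinicalQuestion(question_id=f"q{i + 1:04d}",
                                          keywords=tuple(keywords)))
    return questions


# ---------------------------------------------------------------------------
# Answer planting
# ---------------------------------------------------------------------------

def _keyword_mesh(keywords: Sequence[str], *, use_original: bool,
                  is_major: bool) -> tuple[MeshAssignment, ...]:
    mesh = []
    for kw in keywords:
        norm = normalize_term(kw)
        descriptor = kw if use_original else norm
        entry_terms: frozenset[str] = frozenset()
        if use_original and tokenize(norm) != tokenize(descriptor):
            entry_terms = frozenset({norm})
        mesh.append(MeshAssignment(
            descriptor=descriptor, entry_terms=entry_terms,
            is_major=is_major, subheadings=frozenset(),
        ))
    return tuple(mesh)


def _planted_record(pmid: int, pub_date: _dt.date, question: ClinicalQuestion,
                    config: SimulationConfig, rng: np.random.Generator, *,
                    relevant: bool, quality: bool, pass_through: int) -> CitationRecord:
    """One planted citation passing iteration filters 1..``pass_through`` only."""
    norms = [normalize_term(kw) for kw in question.keywords]
    phrases = norms if not relevant else [*question.keywords, *norms]
    title = " and ".join(dict.fromkeys(phrases))

    noncore = [j for j in config.journal_pool if j not in config.core_journals] \
        or ["Unlisted Specialty Journal"]
    journal = config.core_journals[0]
    mesh_major = True
    pub_types = {"Journal Article", "Randomized Controlled Trial"}
    abstract: str | None = "Planted synthetic abstract."

    if pass_through >= 5:
        pass
    elif pass_through == 4:
        mesh_major = False  # text-word match carries levels 1-4; level 5 fails
    elif pass_through == 3:
        journal = str(_choice(rng, noncore))
    elif pass_through == 2:
        pub_types = {"Journal Article", "Clinical Trial"}  # sensitive, not specific
    else:  # pass_through == 1: fails the sensitive hedge and the abstract rule
        pub_types = {"Journal Article"}
        abstract = None

    synoptic: frozenset[str] = frozenset()
    has_editorial = False
    if quality:
        if rng.random() < config.p_synoptic_given_quality:
            synoptic = frozenset({str(_choice(rng, sorted(DEFAULT_SYNOPTIC_JOURNALS)))})
        else:
            has_editorial = True

    return CitationRecord(
        pmid=pmid,
        doi=f"10.5555/plant.{pmid}",
        title=title,
        abstract=abstract,
        journal=journal,
        pub_date=pub_date,
        mesh_terms=_keyword_mesh(question.keywords, use_original=relevant,
                                 is_major=mesh_major),
        pub_types=frozenset(pub_types),
        synoptic_reviews=synoptic,
        has_editorial=has_editorial,
    )


def plant_answers(corpus: Sequence[CitationRecord], question: ClinicalQuestion,
                  spec: PlantSpec, k: int, *,
                  config: SimulationConfig | None = None,
                  stop_level: int = 5,
                  quality_config: QualityConfig = QualityConfig()) -> list[CitationRecord]:
    """Return a corpus in which the iterative strategy's first ``k`` results
    contain exactly ``spec.n_qualifying_in_topk`` qualifying citations.

    Planted records get the most recent dates (head of the ranking) and
    attributes passing every iteration filter up to ``stop_level``; the
    non-qualifying plants fail level ``stop_level + 1`` so the escalation
    stops there.  Filler plants pad the head of the ranking to ``k`` records,
    and background records that would qualify for this question have their
    quality flags stripped, making the qualifying set exact by construction.
    Corpus size is preserved: the oldest records are displaced.
    """
    if not 1 <= stop_level <= 5:
        raise CorpusError("stop_level must be in 1..5")
    if spec.n_qualifying_in_topk > k:
        raise CorpusError(
            f"cannot plant {spec.n_qualifying_in_topk} qualifying records in top {k}"
        )
    if config is None:
        config = SimulationConfig()
    if spec.n_highq_irrelevant > 0 and not any(
            "neoplasms" in kw.lower() for kw in question.keywords):
        raise CorpusError(
            "high-quality-irrelevant plants need a keyword that changes under "
            "normalization (one containing 'neoplasms'): with identical surface "
            "forms a retrieved record necessarily satisfies the relevance rule"
        )

    rng = _rng(config.seed, _STREAM_PLANT)
    n_filler = max(0, k - spec.n_qualifying_in_topk - spec.n_relevant_lowq
                   - spec.n_highq_irrelevant)
    n_planted = (spec.n_qualifying_in_topk + spec.n_relevant_lowq
                 + spec.n_highq_irrelevant + n_filler)
    if n_planted > len(corpus):
        raise CorpusError("corpus too small to host the planted records")

    max_date = max(r.pub_date for r in corpus)
    max_pmid = max(r.pmid for r in corpus)
    nonq_pass = stop_level if stop_level < 5 else 5
    kinds = (
        [{"relevant": True, "quality": True, "pass_through": 5}]
        * spec.n_qualifying_in_topk
        + [{"relevant": False, "quality": True, "pass_through": nonq_pass}]
        * spec.n_highq_irrelevant
        + [{"relevant": True, "quality": False, "pass_through": nonq_pass}]
        * (spec.n_relevant_lowq + n_filler)
    )
    planted = [
        _planted_record(max_pmid + 1 + i, max_date + _dt.timedelta(days=n_planted - i),
                        question, config, rng, **kind)
        for i, kind in enumerate(kinds)
    ]

    # displace the oldest background records, then scrub would-be qualifiers
    background = sorted(corpus, key=lambda r: (r.pub_date, r.pmid), reverse=True)
    background = background[: len(corpus) - n_planted]
    scrubbed = []
    for rec in background:
        if is_high_quality(rec, quality_config) and is_relevant(rec, question):
            rec = replace(rec, synoptic_reviews=frozenset(), has_editorial=False)
        scrubbed.append(rec)
    return planted + scrubbed


# ---------------------------------------------------------------------------
# Web-result fixtures
# ---------------------------------------------------------------------------

def generate_web_fixture(corpus: Sequence[CitationRecord],
                         question: ClinicalQuestion, n_links: int,
                         p_pmid_link: float, seed: int
                         ) -> tuple[str, list[tuple[str, str]]]:
    """A saved-result-page fixture: ``n_links`` hyperlinks, a known subset
    carrying identifiers of corpus records.

    Returns the HTML document plus the ground-truth list of (kind, value)
    identifiers planted, in order of appearance.
    """
    rng = _rng(seed, _STREAM_WEB)
    order = rng.permutation(len(corpus))
    carriers = iter(order)
    ground_truth: list[tuple[str, str]] = []
    lines = ["<html><body>", f"<h1>results: {' '.join(question.keywords)}</h1>"]
    for i in range(n_links):
        rec = None
        if rng.random() < p_pmid_link:
            idx = next(carriers, None)
            if idx is not None:
                rec = corpus[int(idx)]
        if rec is None:
            lines.append(
                f'<a href="https://example.org/health/topic-{i}">'
                f"Overview of treatment options (entry {i})</a> general text"
            )
            continue
        style = rng.random()
        if rec.doi and style < 0.3:
            lines.append(
                f'<a href="https://doi.org/{rec.doi}">{rec.title}</a> '
                f"doi:{rec.doi}"
            )
            ground_truth.append(("doi", rec.doi))
        elif style < 0.65:
            lines.append(
                f'<a href="https://www.ncbi.nlm.nih.gov/pubmed/{rec.pmid}">'
                f"{rec.title}</a> journal snippet"
            )
            ground_truth.append(("pmid", str(rec.pmid)))
        else:
            lines.append(
                f'<a href="https://example.org/mirror/{i}">{rec.title}</a> '
                f"cited as PMID {rec.pmid}"
            )
            ground_truth.append(("pmid", str(rec.pmid)))
    lines.append("</body></html>")
    return "\n".join(lines), ground_truth
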