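"""Term matching, hedge predicates, plan evaluation and offline ranking."""

import datetime as dt

import pytest
from hypothesis import given, strategies as st

from clinsearch.corpus_model import ClinicalQuestion, CorpusError, MeshAssignment
from clinsearch.query_builder import build_base_query
from clinsearch.retrieval_index import (
    HedgeKind,
    OfflineIndex,
    QueryPlan,
    evaluate_plan,
    execute_offline,
    hedge_predicate,
    match_term,
)
from clinsearch.strategy_engine import iteration_plan
from clinsearch.synthetic_corpus import SimulationConfig, generate_corpus

from conftest import make_record


class TestMatchTerm:
    def test_entry_term_path(self):
        rec = make_record(mesh_terms=(
            MeshAssignment("Thyroid Neoplasms", frozenset({"Thyroid Cancer"})),))
        assert match_term(rec, "thyroid cancer")

    def test_no_field_matches(self):
        rec = make_record(title="Hypertension management", abstract=None)
        assert not match_term(rec, "asthma")

    def test_title_phrase_path_is_contiguous(self):
        rec = make_record(title="Radiation injuries after radiotherapy")
        assert match_term(rec, "radiation injuries")
        assert not match_term(rec, "radiation radiotherapy")

    def test_phrase_does_not_cross_title_abstract_boundary(self):
        rec = make_record(title="Severe radiation", abstract="Injuries were rare")
        assert not match_term(rec, "radiation injuries")

    def test_major_only_restricts_to_major_mesh(self):
        minor = make_record(
            title="Thyroid cancer outcomes",
            mesh_terms=(MeshAssignment("Thyroid Cancer", is_major=False),))
        assert match_term(minor, "thyroid cancer")
        assert not match_term(minor, "thyroid cancer", major_only=True)
        major = make_record(mesh_terms=(
            MeshAssignment("Thyroid Cancer", is_major=True),))
        assert match_term(major, "thyroid cancer", major_only=True)


class TestHedges:
    def test_rct_pub_type_satisfies_specific(self):
        rec = make_record(pub_types=frozenset({"Randomized Controlled Trial"}),
                          title="Some drug study")
        assert hedge_predicate(rec, HedgeKind.SPECIFIC_ONLY)

    def test_editorial_without_trial_vocabulary_fails_sensitive(self):
        rec = make_record(pub_types=frozenset({"Editorial"}),
                          title="Thoughts on care", abstract="An opinion piece.")
        assert not hedge_predicate(rec, HedgeKind.SENSITIVE_ONLY)

    def test_random_prefix_token_satisfies_sensitive(self):
        rec = make_record(title="Patients were randomised to two arms")
        assert hedge_predicate(rec, HedgeKind.SENSITIVE_ONLY)
        assert not hedge_predicate(rec, HedgeKind.SPECIFIC_ONLY)

    def test_therapeutic_use_subheading_satisfies_sensitive(self):
        rec = make_record(title="Drug effects", mesh_terms=(
            MeshAssignment("Metformin", subheadings=frozenset({"therapeutic use"})),))
        assert hedge_predicate(rec, HedgeKind.SENSITIVE_ONLY)

    def test_sysrev_paths(self):
        assert hedge_predicate(
            make_record(pub_types=frozenset({"Meta-Analysis"})), HedgeKind.SYSREV_ONLY)
        assert hedge_predicate(
            make_record(title="Statins: a systematic review"), HedgeKind.SYSREV_ONLY)
        assert hedge_predicate(
            make_record(journal="Cochrane Database of  Systematic Reviews"),
            HedgeKind.SYSREV_ONLY)

    def test_specific_nested_within_sensitive_on_random_records(self, corpus):
        for rec in corpus:
            if hedge_predicate(rec, HedgeKind.SPECIFIC_ONLY):
                assert hedge_predicate(rec, HedgeKind.SENSITIVE_ONLY)


class TestEvaluatePlan:
    @pytest.fixture
    def base(self, thyroid_question):
        return build_base_query(thyroid_question)

    def test_unrestricted_plan_needs_only_base_terms(self, base, rct_record):
        assert evaluate_plan(rct_record, iteration_plan(base, 1))

    def test_abstract_required_at_level_2(self, base, rct_record):
        import dataclasses
        no_abstract = dataclasses.replace(rct_record, abstract=None)
        plan = iteration_plan(base, 2)
        assert evaluate_plan(rct_record, plan)
        assert not evaluate_plan(no_abstract, plan)

    def test_journal_whitelist_enforced_case_insensitively(self, base, rct_record):
        whitelist = frozenset({"the  LANCET"})
        plan = iteration_plan(base, 4, journal_whitelist=whitelist)
        assert evaluate_plan(rct_record, plan)
        plan_other = iteration_plan(base, 4, journal_whitelist=frozenset({"BMJ"}))
        assert not evaluate_plan(rct_record, plan_other)

    def test_excluded_pub_type_rejected(self, base, rct_record):
        import dataclasses
        review = dataclasses.replace(
            rct_record, pub_types=rct_record.pub_types | {"Review"})
        assert not evaluate_plan(review, iteration_plan(base, 2))

    def test_monotone_adding_restrictions_never_grows(self, corpus, thyroid_question):
        base = build_base_query(thyroid_question)
        whitelist = frozenset({"The Lancet", "JAMA", "BMJ"})
        matched = [
            sum(evaluate_plan(r, iteration_plan(base, level, whitelist))
                for r in corpus)
            for level in (1, 2, 3, 4, 5)
        ]
        assert matched == sorted(matched, reverse=True)


class TestExecuteOffline:
    def test_empty_corpus(self, thyroid_question):
        index = OfflineIndex([])
        total, pmids = execute_offline(
            index, iteration_plan(build_base_query(thyroid_question), 1), 50)
        assert (total, pmids) == (0, [])

    def test_date_descending_with_pmid_tiebreak(self):
        recs = [
            make_record(pmid=1, title="asthma care", pub_date=dt.date(2009, 1, 1)),
            make_record(pmid=2, title="asthma care", pub_date=dt.date(2009, 3, 1)),
            make_record(pmid=3, title="asthma care", pub_date=dt.date(2009, 2, 1)),
            make_record(pmid=4, title="asthma care", pub_date=dt.date(2009, 2, 1)),
        ]
        index = OfflineIndex(recs)
        plan = QueryPlan(base=build_base_query(ClinicalQuestion("q", ("asthma",))))
        total, pmids = index.execute(plan, 50)
        assert total == 4
        assert pmids == [2, 4, 3, 1]

    def test_retmax_truncates_but_counts_all(self):
        recs = [make_record(pmid=i, title="asthma care",
                            pub_date=dt.date(2009, 1, i)) for i in (1, 2, 3)]
        index = OfflineIndex(recs)
        plan = QueryPlan(base=build_base_query(ClinicalQuestion("q", ("asthma",))))
        total, pmids = index.execute(plan, 1)
        assert total == 3 and len(pmids) == 1
        with pytest.raises(CorpusError):
            index.execute(plan, 0)

    def test_agrees_with_linear_scan_oracle(self, corpus, thyroid_question):
        """Index output equals a naive filter-sort over the raw records."""
        base = build_base_query(thyroid_question)
        whitelist = frozenset({"The Lancet", "JAMA"})
        index = OfflineIndex(corpus)
        for level in (1, 2, 3, 4, 5):
            plan = iteration_plan(base, level, whitelist)
            matches = [r for r in corpus if evaluate_plan(r, plan)]
            matches.sort(key=lambda r: (r.pub_date, r.pmid), reverse=True)
            total, pmids = index.execute(plan, 50)
            assert total == len(matches)
            assert pmids == [r.pmid for r in matches[:50]]

    def test_repeated_execution_is_deterministic(self, corpus, thyroid_question):
        index = OfflineIndex(corpus)
        plan = QueryPlan(base=build_base_query(thyroid_question))
        assert index.execute(plan, 50) == index.execute(plan, 50)


@given(st.integers(0, 2**31 - 1))
def test_iteration_counts_non_increasing_on_random_corpora(seed):
    """Filter nesting makes per-level hit counts monotone on any corpus."""
    config = SimulationConfig(n_citations=120, seed=seed)
    corpus = generate_corpus(config)
    index = OfflineIndex(corpus)
    base = build_base_query(ClinicalQuestion("q", ("Hypertension",)))
    whitelist = frozenset(config.core_journals)
    counts = [index.execute(iteration_plan(base, level, whitelist), 50)[0]
              for level in (1, 2, 3, 4, 5)]
    assert counts == sorted(counts, reverse=True)
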