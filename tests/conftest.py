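import datetime as dt

import pytest
from hypothesis import settings

from clinsearch.corpus_model import CitationRecord, ClinicalQuestion, MeshAssignment
from clinsearch.synthetic_corpus import SimulationConfig, generate_corpus

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(n_citations=800, n_questions=20, seed=11)


@pytest.fixture(scope="session")
def corpus(sim_config):
    return generate_corpus(sim_config)


@pytest.fixture
def thyroid_question() -> ClinicalQuestion:
    # the worked example: a "neoplasms" keyword exercising normalization
    return ClinicalQuestion("qthyroid", ("Thyroid Neoplasms", "Radiation Injuries"))


def make_record(pmid=10000001, **kwargs) -> CitationRecord:
    defaults = dict(
        title="Treatment outcomes in adults",
        journal="The Lancet",
        pub_date=dt.date(2009, 3, 1),
        abstract="A study abstract.",
    )
    defaults.update(kwargs)
    return CitationRecord(pmid=pmid, **defaults)


@pytest.fixture
def rct_record():
    return make_record(
        title="Thyroid cancer after radiotherapy: a randomized controlled trial",
        pub_types=frozenset({"Randomized Controlled Trial", "Journal Article"}),
        mesh_terms=(
            MeshAssignment("Thyroid Neoplasms", frozenset({"thyroid cancer"}),
                           is_major=True),
            MeshAssignment("Radiation Injuries", is_major=False),
        ),
    )
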