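import datetime as dt

import pytest

from implantwatch import entity_tagging, pipeline, synthetic_ehr
from implantwatch.corpus_io import Note


@pytest.fixture(scope="session")
def lexicon():
    return entity_tagging.load_lexicon()


@pytest.fixture(scope="session")
def small_corpus():
    """A small deterministic synthetic EHR shared across test modules."""
    config = synthetic_ehr.SimConfig(n_patients=30, seed=42)
    return synthetic_ehr.simulate_corpus(config)


@pytest.fixture(scope="session")
def small_candidates(small_corpus, lexicon):
    corpus, _ = small_corpus
    return pipeline.corpus_candidates(corpus, lexicon)


def make_note(text, created="2010-06-15T12:00:00", note_id="n1", patient_id="p1",
              note_class="clinical_note"):
    return Note(patient_id, note_id, dt.datetime.fromisoformat(created), text, note_class)


@pytest.fixture
def note_factory():
    return make_note
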