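import numpy as np
import pytest

from memotrace.normalize import build_extraction_table
from memotrace.ontology import to_bio
from memotrace.synthetic import GeneratorConfig, annotated_corpus, generate


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-patient synthetic EHR shared across tests."""
    return generate(GeneratorConfig(n_patients=60, seed=101))


@pytest.fixture(scope="session")
def small_extractions(small_dataset):
    return build_extraction_table(small_dataset.notes)


@pytest.fixture(scope="session")
def tiny_tagger():
    """A quickly trained tagger on a small template corpus (shared)."""
    from memotrace.tagger import TaggerConfig, train
    notes = annotated_corpus(120, seed=7)
    corpus = [to_bio(n) for n in notes]
    cfg = TaggerConfig(word_dim=24, char_dim=8, char_hidden=8, hidden=32,
                       epochs=40, patience=10, dropout=0.2, lr=5e-3, seed=3)
    return train(corpus, cfg, split=0.8)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
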