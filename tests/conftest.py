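import numpy as np
import pytest

from mirlsi.corpus import build_entity_documents
from mirlsi.lsi import fit_lsi
from mirlsi.synthetic import SyntheticCorpusConfig, generate_synthetic_corpus
from mirlsi.vectorize import build_term_document_matrix, default_stoplist
from mirlsi.weighting import apply_log_entropy


@pytest.fixture(scope="session")
def planted_corpus():
    """Default synthetic corpus: 5 topics x 10 entities, fixed seed."""
    config = SyntheticCorpusConfig(seed=0)
    citations, cmap, labels = generate_synthetic_corpus(config)
    return config, citations, cmap, labels


@pytest.fixture(scope="session")
def planted_model(planted_corpus):
    """Entropy-truncated LSI model fitted on the planted corpus."""
    _, citations, cmap, labels = planted_corpus
    docs = build_entity_documents(citations, cmap)
    tdm = build_term_document_matrix(docs, default_stoplist())
    weighted = apply_log_entropy(tdm)
    model, summary = fit_lsi(weighted)
    return model, summary, labels


@pytest.fixture(scope="session")
def toy_weighted():
    """Small dense-ish weighted matrix from a 3-document toy corpus."""
    from mirlsi.corpus import EntityDocument

    docs = [
        EntityDocument("ent-a", "apoptosis tumor growth apoptosis signaling", 1),
        EntityDocument("ent-b", "tumor suppressor gene expression tumor", 1),
        EntityDocument("ent-c", "neuron synapse signaling plasticity neuron", 1),
    ]
    tdm = build_term_document_matrix(docs)
    return tdm, apply_log_entropy(tdm)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
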