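import numpy as np
import pytest

import gtmview as gv

PAPER_GRID = (20, 20)   # J = 400
PAPER_BASIS = (4, 4)    # K = 16


@pytest.fixture(scope="session")
def five_clusters():
    """The three-dimensional five-cluster Gaussian testbed."""
    data, labels = gv.simulate_clusters(seed=1)
    return data, labels


@pytest.fixture(scope="session")
def fitted_model(five_clusters):
    """GTM fit of the testbed at the reference configuration K=16, J=400."""
    data, labels = five_clusters
    lattice = gv.make_grid(PAPER_GRID)
    basis = gv.make_basis(lattice, PAPER_BASIS)
    model, trace = gv.fit(data, lattice, basis)
    return model, trace, data, labels


@pytest.fixture(scope="session")
def topic_corpus():
    """Synthetic 4-topic corpus with known planted vocabularies."""
    docs, counts, planted = gv.synthetic_corpus(seed=0)
    return docs, counts, planted


@pytest.fixture(scope="session")
def corpus_model(topic_corpus):
    """GTM trained on the ImpI-weighted features of the synthetic corpus."""
    _, counts, planted = topic_corpus
    scores = gv.impi_scores(counts)
    weighted = gv.weighted_frequencies(counts, scores)
    data = gv.DataMatrix(weighted.values, ids=weighted.doc_ids)
    lattice = gv.make_grid(PAPER_GRID)
    basis = gv.make_basis(lattice, PAPER_BASIS)
    model, trace = gv.fit(data, lattice, basis)
    return model, data, weighted, planted


def small_random_model(rng, p=3, grid=(3, 3), basis_shape=(2, 2)):
    """A small random GTM for oracle checks."""
    lattice = gv.make_grid(grid)
    basis = gv.make_basis(lattice, basis_shape)
    W = rng.standard_normal((p, basis.n_centers))
    phi = gv.design_matrix(basis, lattice)
    return gv.GTMModel(lattice=lattice, basis=basis, W=W,
                       beta=float(rng.uniform(0.5, 3.0)),
                       manifold=W @ phi.T)
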