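"""Synthetic datasets: the five-cluster Gaussian testbed and a topic corpus.

``simulate_clusters`` emulates the classic topographic-recovery testbed: a
three-dimensional sample from five multivariate normals forming two groups
that sit in opposite corners of the data cube (clusters 1-3 in one corner,
4-5 in the other), with unit isotropic covariance and inter-center spacing
of at least six standard deviations so the clusters are well separated.

``synthetic_corpus`` builds a topic-structured term-document count matrix:
each topic owns a disjoint block of planted terms drawn Poisson(lambda_hi)
in its own documents (and absent elsewhere), on top of a shared background
vocabulary drawn Poisson(lambda_lo) everywhere.  Ground-truth topic
vocabularies are returned so tests can check recovery.  It models count
structure only, not the semantics of real abstracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import DataMatrix
from .text import TermDocCounts

__all__ = [
    "ClusterSpec",
    "CorpusSpec",
    "default_cluster_spec",
    "simulate_clusters",
    "synthetic_corpus",
]

_DEFAULT_CENTERS = (
    (-7.0, -7.0, -7.0),
    (-7.0, -1.0, -7.0),
    (-1.0, -7.0, -7.0),
    (7.0, 7.0, 7.0),
    (7.0, 1.0, 7.0),
)

# letter-only term codes (no vowel suffixes, so stemming leaves them alone)
_LETTERS = "bcdfghjklmnpqrstvwz"


@dataclass(frozen=True)
class ClusterSpec:
    """Gaussian mixture specification for the cluster testbed."""

    centers: tuple[tuple[float, ...], ...] = _DEFAULT_CENTERS
    covariances: tuple | None = None  # per-cluster p x p SPD; None = identity
    sizes: tuple[int, ...] = (50, 50, 50, 50, 50)
    seed: int = 0

    def __post_init__(self):
        if len(self.centers) < 1:
            raise ValueError("need at least one cluster")
        if len(self.sizes) != len(self.centers):
            raise ValueError("sizes must match centers")
        if any(s < 1 for s in self.sizes):
            raise ValueError("cluster sizes must be positive")


@dataclass(frozen=True)
class CorpusSpec:
    n_topics: int = 4
    docs_per_topic: int = 15
    vocab_per_topic: int = 10
    background_vocab: int = 60
    lambda_hi: float = 8.0
    lambda_lo: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_topics, self.docs_per_topic, self.vocab_per_topic,
               self.background_vocab) < 1:
            raise ValueError("corpus dimensions must be positive")
        if self.lambda_hi <= 0 or self.lambda_lo <= 0:
            raise ValueError("count rates must be positive")


def default_cluster_spec(seed: int = 0) -> ClusterSpec:
    return ClusterSpec(seed=seed)


def simulate_clusters(spec: ClusterSpec | None = None,
                      seed: int | None = None
                      ) -> tuple[DataMatrix, np.ndarray]:
    """Draw the Gaussian cluster testbed; deterministic per seed.

    Returns the data (p x N internally; IDs "obs0001"...) and integer
    cluster labels 1..n_clusters.
    """
    spec = spec or default_cluster_spec()
    if seed is not None:
        spec = ClusterSpec(centers=spec.centers, covariances=spec.covariances,
                           sizes=spec.sizes, seed=seed)
    rng = np.random.default_rng(spec.seed)
    centers = np.asarray(spec.centers, dtype=float)
    p = centers.shape[1]
    chunks, labels = [], []
    for c, (center, size) in enumerate(zip(centers, spec.sizes)):
        if spec.covariances is None:
            cov_chol = np.eye(p)
        else:
            cov = np.asarray(spec.covariances[c], dtype=float)
            try:
                cov_chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError as err:
                raise ValueError(f"covariance {c} is not SPD") from err
        z = rng.standard_normal((size, p))
        chunks.append(center[None, :] + z @ cov_chol.T)
        labels.extend([c + 1] * size)
    rows = np.vstack(chunks)
    ids = [f"obs{i + 1:04d}" for i in range(rows.shape[0])]
    return DataMatrix.from_rows(rows, ids=ids), np.asarray(labels)


def _term_code(prefix: str, i: int) -> str:
    # base-19 letter code, fixed width 3
    digits = []
    for _ in range(3):
        digits.append(_LETTERS[i % len(_LETTERS)])
        i //= len(_LETTERS)
    return prefix + "".join(reversed(digits))


def synthetic_corpus(spec: CorpusSpec | None = None,
                     seed: int | None = None
                     ) -> tuple[list[str], TermDocCounts, dict[str, tuple[str, ...]]]:
    """Generate a topic-structured corpus; deterministic per seed.

    Returns (documents as plain text, the exact count matrix the documents
    realise, and the planted topic vocabularies keyed "topic0", ...).
    """
    spec = spec or CorpusSpec()
    if seed is not None:
        spec = CorpusSpec(n_topics=spec.n_topics,
                          docs_per_topic=spec.docs_per_topic,
                          vocab_per_topic=spec.vocab_per_topic,
                          background_vocab=spec.background_vocab,
                          lambda_hi=spec.lambda_hi, lambda_lo=spec.lambda_lo,
                          seed=seed)
    rng = np.random.default_rng(spec.seed)
    topic_terms = {
        f"topic{t}": tuple(_term_code(f"q{_LETTERS[t]}", i)
                           for i in range(spec.vocab_per_topic))
        for t in range(spec.n_topics)
    }
    background = tuple(_term_code("xw", i) for i in range(spec.background_vocab))
    vocab = tuple(sorted(set(background)
                         | {t for ts in topic_terms.values() for t in ts}))
    index = {t: i for i, t in enumerate(vocab)}
    n_docs = spec.n_topics * spec.docs_per_topic
    counts = np.zeros((len(vocab), n_docs), dtype=np.int64)
    doc_topics = []
    for t in range(spec.n_topics):
        for d in range(spec.docs_per_topic):
            j = t * spec.docs_per_topic + d
            doc_topics.append(t)
            for term in topic_terms[f"topic{t}"]:
                counts[index[term], j] = rng.poisson(spec.lambda_hi)
            for term in background:
                counts[index[term], j] = rng.poisson(spec.lambda_lo)
    doc_ids = tuple(f"doc{j:03d}" for j in range(n_docs))
    documents = []
    for j in range(n_docs):
        toks = []
        for i, term in enumerate(vocab):
            toks.extend([term] * int(counts[i, j]))
        documents.append(" ".join(toks))
    tdc = TermDocCounts(counts, vocab, doc_ids)
    return documents, tdc, topic_terms
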