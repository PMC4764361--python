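"""Term-document counting and the ImpI (importance index) statistic.

ImpI is a Gini-style dispersion measure of a term's frequencies across a
corpus: for term e_i occurring f_ij times in document d_j,

    ImpI_i = sum_j sum_k |f_ij - f_ik| / (2 N^2 mu_i),      mu_i = mean_j f_ij.

A term spread evenly over all documents scores 0; a term concentrated in a
single document is maximal.  Note the N^2 denominator (the population-Gini
form, the "printed" dialect) tops out at (N-1)/N for a single-document term;
the sample-corrected denominator 2 N (N-1) mu_i (dialect "corrected") makes
that endpoint exactly 1.  Both dialects are available everywhere.

The ImpI-weighted frequency used as the model feature is
f*_ij = ImpI_i * f_ij * F / (||d_j|| * ||e_i||), an observed/expected lift
with ||d_j|| the document total, ||e_i|| the term total and F the grand
total; the alternative grouping f = ImpI_i * f_ij / (||d_j|| ||e_i|| F) is
available behind ``reading="scaled"``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from ._stem import porter_stem

__all__ = [
    "TermDocCounts",
    "ImpIVector",
    "WeightedTermDoc",
    "default_stopwords",
    "preprocess",
    "impi_scores",
    "select_top",
    "weighted_frequencies",
]

_TOKEN = re.compile(r"[a-z]+")

DIALECTS = ("printed", "corrected")


@dataclass(frozen=True)
class TermDocCounts:
    """Raw term x document frequency matrix with its labels."""

    counts: np.ndarray  # n_terms x n_docs, nonnegative
    vocabulary: tuple[str, ...]
    doc_ids: tuple[str, ...]

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be 2-D (terms x documents)")
        if np.any(c < 0):
            raise ValueError("counts must be nonnegative")
        if len(self.vocabulary) != c.shape[0]:
            raise ValueError("vocabulary length must match count rows")
        if len(self.doc_ids) != c.shape[1]:
            raise ValueError("doc_ids length must match count columns")
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise ValueError("vocabulary terms must be unique")
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "vocabulary", tuple(self.vocabulary))
        object.__setattr__(self, "doc_ids", tuple(self.doc_ids))

    @property
    def n_terms(self) -> int:
        return self.counts.shape[0]

    @property
    def n_docs(self) -> int:
        return self.counts.shape[1]

    def subset(self, term_indices: Sequence[int]) -> "TermDocCounts":
        idx = list(term_indices)
        return TermDocCounts(self.counts[idx, :],
                             tuple(self.vocabulary[i] for i in idx),
                             self.doc_ids)


@dataclass(frozen=True)
class ImpIVector:
    """Per-term importance scores; NaN marks terms with zero mean frequency."""

    scores: np.ndarray
    dialect: str
    terms: tuple[str, ...] | None = None


@dataclass(frozen=True)
class WeightedTermDoc:
    """ImpI-weighted frequencies f* with the norms used to compute them."""

    values: np.ndarray  # n_terms x n_docs
    doc_norms: np.ndarray
    term_norms: np.ndarray
    total: float
    vocabulary: tuple[str, ...]
    doc_ids: tuple[str, ...]


def default_stopwords() -> frozenset[str]:
    """The standard English stopword list shipped with the package."""
    txt = resources.files("gtmview").joinpath("data/stopwords.txt").read_text()
    return frozenset(w for w in txt.split() if w)


def tokenize(text: str, stopwords: frozenset[str] | None = None,
             stem: bool = True) -> list[str]:
    """Lowercase, split on non-letter boundaries, drop stopwords, stem."""
    stopwords = default_stopwords() if stopwords is None else stopwords
    toks = _TOKEN.findall(text.lower())
    toks = [t for t in toks if t not in stopwords]
    if stem:
        toks = [porter_stem(t) for t in toks]
    return toks


def preprocess(documents: Sequence[str],
               stopwords: Iterable[str] | None = None,
               stem: bool = True,
               doc_ids: Sequence[str] | None = None) -> TermDocCounts:
    """Count terms per document after stopword removal and suffix stemming.

    Vocabulary is sorted, so repeated runs give identical matrices.
    Documents that reduce to nothing keep an (all-zero) column and are
    flagged with a warning.
    """
    documents = list(documents)
    if not documents:
        raise ValueError("empty corpus")
    sw = default_stopwords() if stopwords is None else frozenset(
        w.lower() for w in stopwords)
    if doc_ids is None:
        doc_ids = tuple(f"d{j}" for j in range(len(documents)))
    per_doc: list[dict[str, int]] = []
    vocab: set[str] = set()
    for text in documents:
        counts: dict[str, int] = {}
        for tok in tokenize(text, sw, stem):
            counts[tok] = counts.get(tok, 0) + 1
        per_doc.append(counts)
        vocab.update(counts)
    if not vocab:
        raise ValueError("corpus contains no countable terms")
    terms = tuple(sorted(vocab))
    index = {t: i for i, t in enumerate(terms)}
    mat = np.zeros((len(terms), len(documents)), dtype=np.int64)
    for j, counts in enumerate(per_doc):
        if not counts:
            warnings.warn(f"document {doc_ids[j]!r} is empty after "
                          "preprocessing", UserWarning, stacklevel=2)
        for t, c in counts.items():
            mat[index[t], j] = c
    return TermDocCounts(mat, terms, tuple(doc_ids))


def _counts_and_terms(counts) -> tuple[np.ndarray, tuple[str, ...] | None]:
    if isinstance(counts, TermDocCounts):
        return np.asarray(counts.counts, dtype=float), counts.vocabulary
    return np.asarray(counts, dtype=float), None


def impi_scores(counts, dialect: str = "printed") -> ImpIVector:
    """ImpI for every term: mean absolute pairwise frequency difference,
    normalised by twice the mean frequency.

    dialect "printed" divides by 2 N^2 mu_i; "corrected" by 2 N (N-1) mu_i.
    Scores are invariant to positive rescaling of the frequencies.  Terms
    with mu_i = 0 have no defined score and are reported as NaN.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"dialect must be one of {DIALECTS}")
    f, terms = _counts_and_terms(counts)
    if f.ndim == 1:
        f = f[None, :]
    n_terms, N = f.shape
    mu = f.mean(axis=1)
    scores = np.full(n_terms, np.nan)
    # double sum of |f_ij - f_ik| over ordered pairs, vectorised in chunks
    denom_n = 2.0 * N * N if dialect == "printed" else 2.0 * N * (N - 1)
    chunk = max(1, int(2_000_000 // (N * N + 1)))
    for start in range(0, n_terms, chunk):
        blk = f[start:start + chunk]
        s = np.abs(blk[:, :, None] - blk[:, None, :]).sum(axis=(1, 2))
        m = mu[start:start + chunk]
        ok = m > 0
        vals = np.full(blk.shape[0], np.nan)
        vals[ok] = s[ok] / (denom_n * m[ok])
        scores[start:start + chunk] = vals
    attach = terms if terms is not None else None
    return ImpIVector(scores=scores, dialect=dialect, terms=attach)


def select_top(impi: ImpIVector, n: int = 1000) -> list[int]:
    """Indices of the n highest-scoring terms (ties lexicographic by term).

    Terms without a defined score are never selected; n is capped at the
    number of scored terms.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    scores = impi.scores
    valid = np.flatnonzero(np.isfinite(scores))
    if impi.terms is not None:
        keys = sorted(valid, key=lambda i: (-scores[i], impi.terms[i]))
    else:
        keys = sorted(valid, key=lambda i: (-scores[i], i))
    return [int(i) for i in keys[:n]]


def weighted_frequencies(counts, impi: ImpIVector,
                         reading: str = "lift") -> WeightedTermDoc:
    """ImpI-weighted frequency matrix f*.

    reading "lift" (default): f*_ij = ImpI_i f_ij F / (||d_j|| ||e_i||);
    reading "scaled": f*_ij = ImpI_i f_ij / (||d_j|| ||e_i|| F).
    Zero counts stay exactly zero; documents with zero total are dropped
    with a warning.
    """
    if reading not in ("lift", "scaled"):
        raise ValueError("reading must be 'lift' or 'scaled'")
    f, terms = _counts_and_terms(counts)
    if isinstance(counts, TermDocCounts):
        doc_ids = counts.doc_ids
    else:
        doc_ids = tuple(f"d{j}" for j in range(f.shape[1]))
    if terms is None:
        terms = tuple(f"t{i}" for i in range(f.shape[0]))
    scores = np.nan_to_num(impi.scores, nan=0.0)
    if scores.shape[0] != f.shape[0]:
        raise ValueError("ImpI vector length must match count rows")
    d_norm = f.sum(axis=0)
    keep = d_norm > 0
    if not np.all(keep):
        warnings.warn(f"dropping {int((~keep).sum())} document(s) with zero "
                      "term total", UserWarning, stacklevel=2)
        f = f[:, keep]
        d_norm = d_norm[keep]
        doc_ids = tuple(d for d, k in zip(doc_ids, keep) if k)
    e_norm = f.sum(axis=1)
    F = float(f.sum())
    safe_e = np.where(e_norm > 0, e_norm, 1.0)
    if reading == "lift":
        vals = scores[:, None] * f * F / (d_norm[None, :] * safe_e[:, None])
    else:
        vals = scores[:, None] * f / (d_norm[None, :] * safe_e[:, None] * F)
    vals[f == 0] = 0.0
    return WeightedTermDoc(values=vals, doc_norms=d_norm, term_norms=e_norm,
                           total=F, vocabulary=terms, doc_ids=doc_ids)
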