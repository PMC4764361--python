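"""Interpreting the latent space of a text-trained GTM.

Two complementary views: *tagging* labels an arbitrary latent location r+
with the top terms of its mapped manifold point y+ = W Phi(r+) (when the
model is trained on ImpI-weighted term features, y+ is a vector of term
scores); *cluster keywords* runs k-means on the 2-D projection and ranks
terms per cluster by the sum of the members' ImpI-weighted vectors, then
separates out the terms shared by every cluster so the remaining lists
discriminate between clusters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans

from .core import GTMModel, manifold_at
from .text import WeightedTermDoc

__all__ = ["Tag", "ClusterKeywords", "tag_latent_point", "cluster_keywords"]


@dataclass(frozen=True)
class Tag:
    latent_point: np.ndarray
    manifold_point: np.ndarray
    top_terms: tuple[tuple[str, float], ...]


@dataclass(frozen=True)
class ClusterKeywords:
    labels: np.ndarray  # cluster assignment per document
    cluster_terms: tuple[tuple[str, ...], ...]  # per cluster, shared removed
    shared_terms: tuple[str, ...]
    raw_top_terms: tuple[tuple[str, ...], ...]  # before shared-term deletion


def _rank_terms(scores: np.ndarray, vocabulary: Sequence[str],
                m: int) -> list[tuple[str, float]]:
    order = sorted(range(len(vocabulary)),
                   key=lambda i: (-scores[i], vocabulary[i]))
    return [(vocabulary[i], float(scores[i])) for i in order[:m]]


def tag_latent_point(model: GTMModel, r_plus, vocabulary: Sequence[str],
                     m: int = 10) -> Tag:
    """Label latent location r+ with the top-m terms of y+ = W Phi(r+).

    The evaluation includes any user-added attractors and stage-3 manifold
    blends, so tags reflect the view the user currently sees.  Ties are
    broken lexicographically.
    """
    r_plus = np.asarray(r_plus, dtype=float).reshape(-1)
    vocabulary = list(vocabulary)
    if len(vocabulary) != model.n_vars:
        raise ValueError(
            f"vocabulary has {len(vocabulary)} terms but the model maps to "
            f"{model.n_vars} variables")
    y_plus = manifold_at(model, r_plus[:, None])[:, 0]
    top = _rank_terms(y_plus, vocabulary, min(m, len(vocabulary)))
    return Tag(latent_point=r_plus, manifold_point=y_plus,
               top_terms=tuple(top))


def cluster_keywords(coordinates, weighted, vocabulary: Sequence[str] | None = None,
                     k: int = 4, top_m: int = 10, seed: int = 0,
                     max_retries: int = 5) -> ClusterKeywords:
    """k-means the projected documents, then extract per-cluster keywords.

    Clusters the N x 2 latent coordinates (Lloyd's k-means, 10 restarts,
    fixed seed); within each cluster, terms are ranked by the sum of the
    ImpI-weighted document vectors over members; the top-m lists are
    reported with the terms present in every cluster's list pulled out into
    a separate shared list.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    coords = np.asarray(coordinates, dtype=float)
    if isinstance(weighted, WeightedTermDoc):
        values = weighted.values
        if vocabulary is None:
            vocabulary = weighted.vocabulary
    else:
        values = np.asarray(weighted, dtype=float)
    if vocabulary is None:
        raise ValueError("vocabulary required when weighted is a bare matrix")
    vocabulary = list(vocabulary)
    if coords.shape[0] != values.shape[1]:
        raise ValueError("coordinates and weighted counts must align on "
                         "documents")
    labels = None
    for attempt in range(max_retries):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed + attempt,
                    algorithm="lloyd")
        cand = km.fit_predict(coords)
        if len(np.unique(cand)) == k:
            labels = cand
            break
    if labels is None:
        raise RuntimeError(f"k-means produced an empty cluster in "
                           f"{max_retries} attempts")
    raw_lists = []
    for c in range(k):
        member_sum = values[:, labels == c].sum(axis=1)
        raw_lists.append(tuple(t for t, _ in
                               _rank_terms(member_sum, vocabulary, top_m)))
    shared = set(raw_lists[0])
    for lst in raw_lists[1:]:
        shared &= set(lst)
    shared_terms = tuple(sorted(shared))
    cluster_terms = tuple(tuple(t for t in lst if t not in shared)
                          for lst in raw_lists)
    return ClusterKeywords(labels=labels, cluster_terms=cluster_terms,
                           shared_terms=shared_terms,
                           raw_top_terms=tuple(raw_lists))
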