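"""Condition clustering on fPC score vectors.

Conditions (or cells) are compared by the Pearson correlation of their full
fPC score vectors and grouped by a mutual k-nearest-neighbour graph: two
items are joined iff each ranks the other among its k most similar
neighbours, and clusters are the connected components of that graph.  The
procedure needs only a neighbour count and a similarity, is fully
deterministic (ties in neighbour ranking are broken by item order), and
makes no assumption about cluster shape.  A k-means-with-silhouette
fallback is provided for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["ClusterResult", "score_similarity", "knn_cluster", "kmeans_silhouette_cluster"]


@dataclass
class ClusterResult:
    """A hard partition of items with the similarity it was derived from."""

    items: list[str]
    labels: np.ndarray          # cluster index per item, 1..n_clusters
    n_clusters: int
    similarity: np.ndarray
    params: dict = field(default_factory=dict)

    def assignments(self) -> dict[str, int]:
        return {it: int(lb) for it, lb in zip(self.items, self.labels)}


def _distance_similarity(vectors: np.ndarray) -> np.ndarray:
    """Euclidean distances mapped to (0, 1] via exp(-d / mean nonzero d)."""
    d = np.sqrt(((vectors[:, None, :] - vectors[None, :, :]) ** 2).sum(-1))
    nz = d[d > 0]
    scale = nz.mean() if nz.size else 1.0
    return np.exp(-d / scale)


def score_similarity(score_vectors: np.ndarray) -> tuple[np.ndarray, dict]:
    """Similarity matrix over items from their score vectors.

    With >= 3 score dimensions, entries are Pearson correlations across
    dimensions; in lower dimension (where correlation across dimensions is
    meaningless) a scaled-Euclidean similarity in (0, 1] is used instead.
    Zero-variance vectors force the distance mode with a warning.  Returns
    the matrix and a params dict recording the mode.
    """
    V = np.asarray(score_vectors, dtype=float)
    if V.ndim != 2 or V.shape[0] < 2:
        raise ValueError("need >= 2 items of equal-length score vectors")
    n, d = V.shape
    mode = "pearson" if d >= 3 else "scaled_euclidean"
    if mode == "pearson" and np.any(V.std(axis=1) == 0):
        warnings.warn("zero-variance score vector: falling back to distance similarity")
        mode = "scaled_euclidean"
    if mode == "pearson":
        S = np.corrcoef(V)
        np.fill_diagonal(S, 1.0)
    else:
        S = _distance_similarity(V)
    return S, {"mode": mode, "n_dims": d}


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def knn_cluster(
    similarity: np.ndarray,
    k_neighbors: int,
    items: Sequence[str] | None = None,
) -> ClusterResult:
    """Cluster items as connected components of the mutual-KNN graph.

    An edge joins i and j iff each is among the other's ``k_neighbors`` most
    similar items (self excluded).  Neighbour ties are broken by item index
    order, making the partition deterministic.  Cluster labels are contiguous
    from 1, ordered by each cluster's first item.
    """
    S = np.asarray(similarity, dtype=float)
    n = S.shape[0]
    if S.shape != (n, n):
        raise ValueError("similarity must be square")
    if not 1 <= k_neighbors < n:
        raise ValueError(f"k_neighbors must be in [1, {n - 1}]")
    items = [f"item{i}" for i in range(n)] if items is None else list(items)
    if len(items) != n:
        raise ValueError("items length must match similarity size")

    neighbor_sets = []
    for i in range(n):
        order = sorted((j for j in range(n) if j != i), key=lambda j: (-S[i, j], j))
        neighbor_sets.append(set(order[:k_neighbors]))

    uf = _UnionFind(n)
    for i in range(n):
        for j in neighbor_sets[i]:
            if i in neighbor_sets[j]:
                uf.union(i, j)

    roots: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i in range(n):
        r = uf.find(i)
        if r not in roots:
            roots[r] = len(roots) + 1
        labels[i] = roots[r]

    return ClusterResult(
        items=items, labels=labels, n_clusters=len(roots), similarity=S,
        params={"k_neighbors": k_neighbors, "linkage": "mutual_knn_components"},
    )


def kmeans_silhouette_cluster(
    score_vectors: np.ndarray,
    k_range: Sequence[int] = range(2, 9),
    items: Sequence[str] | None = None,
    seed: int = 0,
) -> ClusterResult:
    """Sensitivity-analysis fallback: k-means with silhouette model selection."""
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    V = np.asarray(score_vectors, dtype=float)
    items = [f"item{i}" for i in range(V.shape[0])] if items is None else list(items)
    best = None
    for k in k_range:
        if k >= V.shape[0]:
            continue
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(V)
        score = silhouette_score(V, km.labels_)
        if best is None or score > best[0]:
            best = (score, k, km.labels_)
    if best is None:
        raise ValueError("no feasible k in k_range")
    _, k, raw = best
    remap: dict[int, int] = {}
    labels = np.empty(V.shape[0], dtype=int)
    for i, lb in enumerate(raw):
        if lb not in remap:
            remap[lb] = len(remap) + 1
        labels[i] = remap[lb]
    S, sim_params = score_similarity(V)
    return ClusterResult(
        items=items, labels=labels, n_clusters=k, similarity=S,
        params={"method": "kmeans_silhouette", "k": k, **sim_params},
    )
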