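"""Ward hierarchical clustering of regions and the optimal-k index vote.

Regions are agglomerated with Ward's minimum-variance criterion applied to
the supplied (unsquared) dissimilarities — the Ward.D2 dialect, the dominant
modern convention.  The number of networks is chosen by majority vote of
five internal validity indices evaluated on the Ward labels for every
candidate k:

* pseudo-F (Calinski-Harabasz computed from pairwise distances)  — maximize
* average silhouette width                                        — maximize
* Davies-Bouldin with medoid centres                              — minimize
* Dunn index                                                      — maximize
* C-index                                                         — minimize

Each index votes for its best k; the majority wins, ties broken toward the
smaller k (parsimony).  The per-index scores and votes are reported so a
divergent vote can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_score

__all__ = [
    "ward_tree",
    "cut_tree_labels",
    "select_optimal_k",
    "ClusterSolution",
    "WardNetworkClusterer",
]


def _check_dissimilarity(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    if d.shape[0] < 2:
        raise ValueError("need >= 2 regions")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if np.any(d < 0):
        raise ValueError("dissimilarity must be nonnegative")
    if not np.allclose(np.diag(d), 0.0, atol=1e-12):
        raise ValueError("dissimilarity must have a zero diagonal")
    return d


def ward_tree(d: np.ndarray) -> np.ndarray:
    """Full Ward agglomeration of a dissimilarity matrix.

    Returns the scipy linkage matrix (merge pairs and heights); heights are
    non-decreasing under Ward's criterion.
    """
    d = _check_dissimilarity(d)
    return hierarchy.linkage(squareform(d, checks=False), method="ward")


def cut_tree_labels(linkage: np.ndarray, k: int) -> np.ndarray:
    """Labels induced by removing the k-1 highest merges.

    Labels are renumbered 0..k-1 by first occurrence, so they are invariant
    to the arbitrary cluster numbering of the tree.
    """
    n = linkage.shape[0] + 1
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    raw = hierarchy.fcluster(linkage, t=k, criterion="maxclust")
    order: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, c in enumerate(raw):
        labels[i] = order.setdefault(c, len(order))
    return labels


# ---------------------------------------------------------------------------
# Internal validity indices, all computed from the distance matrix alone.

def _within_between_masks(labels: np.ndarray) -> np.ndarray:
    return labels[:, None] == labels[None, :]


def _pseudo_f(d: np.ndarray, labels: np.ndarray) -> float:
    """Calinski-Harabasz pseudo-F from squared pairwise distances."""
    n = len(labels)
    k = len(np.unique(labels))
    d2 = d**2
    total_ss = d2[np.triu_indices(n, 1)].sum() / n
    within = 0.0
    for c in np.unique(labels):
        idx = np.nonzero(labels == c)[0]
        if len(idx) > 1:
            sub = d2[np.ix_(idx, idx)]
            within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    between = total_ss - within
    if within <= 0 or n == k:
        return np.inf
    return (between / (k - 1)) / (within / (n - k))


def _silhouette(d: np.ndarray, labels: np.ndarray) -> float:
    return float(silhouette_score(d, labels, metric="precomputed"))


def _davies_bouldin(d: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin with medoid centres (distance-matrix variant)."""
    clusters = np.unique(labels)
    medoids, scatter = [], []
    for c in clusters:
        idx = np.nonzero(labels == c)[0]
        sums = d[np.ix_(idx, idx)].sum(axis=1)
        med = idx[int(np.argmin(sums))]
        medoids.append(med)
        scatter.append(d[idx, med].mean())
    ratios = []
    for a in range(len(clusters)):
        worst = 0.0
        for b in range(len(clusters)):
            if a == b:
                continue
            sep = d[medoids[a], medoids[b]]
            worst = max(worst, (scatter[a] + scatter[b]) / sep if sep > 0 else np.inf)
        ratios.append(worst)
    return float(np.mean(ratios))


def _dunn(d: np.ndarray, labels: np.ndarray) -> float:
    same = _within_between_masks(labels)
    off = ~np.eye(len(labels), dtype=bool)
    diam = d[same & off].max() if np.any(same & off) else 0.0
    sep = d[~same].min()
    return float(sep / diam) if diam > 0 else np.inf


def _c_index(d: np.ndarray, labels: np.ndarray) -> float:
    iu = np.triu_indices(len(labels), 1)
    all_d = d[iu]
    within_mask = (labels[iu[0]] == labels[iu[1]])
    n_w = int(within_mask.sum())
    if n_w == 0:
        return np.inf
    s = all_d[within_mask].sum()
    ordered = np.sort(all_d)
    s_min = ordered[:n_w].sum()
    s_max = ordered[-n_w:].sum()
    if s_max == s_min:
        return np.inf
    return float((s - s_min) / (s_max - s_min))


#: index name -> (function, direction); +1 maximize, -1 minimize
INDEX_BATTERY = {
    "pseudo_f": (_pseudo_f, +1),
    "silhouette": (_silhouette, +1),
    "davies_bouldin": (_davies_bouldin, -1),
    "dunn": (_dunn, +1),
    "c_index": (_c_index, -1),
}


def select_optimal_k(
    d: np.ndarray, k_range=tuple(range(2, 11)), linkage: np.ndarray | None = None
) -> tuple[int, pd.DataFrame]:
    """Majority vote of the validity-index battery over candidate k.

    Returns ``(k_star, votes)`` where ``votes`` has one row per index with
    its score at every k and its preferred k.  Ties (within an index and in
    the final vote) break toward smaller k.
    """
    d = _check_dissimilarity(d)
    n = d.shape[0]
    k_range = sorted({int(k) for k in k_range})
    if not k_range or k_range[0] < 2 or k_range[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    iu = np.triu_indices(n, 1)
    if np.ptp(d[iu]) == 0.0:
        raise ValueError("degenerate dissimilarity: all distances equal")
    if linkage is None:
        linkage = ward_tree(d)
    labels_by_k = {k: cut_tree_labels(linkage, k) for k in k_range}

    rows = []
    for name, (fn, direction) in INDEX_BATTERY.items():
        scores = {k: fn(d, labels_by_k[k]) for k in k_range}
        finite = {k: v for k, v in scores.items() if np.isfinite(v)}
        pool = finite if finite else scores
        best_val = max(pool.values()) if direction > 0 else min(pool.values())
        preferred = min(k for k, v in pool.items() if v == best_val)
        rows.append({"index": name, **{f"k={k}": scores[k] for k in k_range},
                     "preferred_k": preferred})
    votes = pd.DataFrame(rows)
    counts = votes["preferred_k"].value_counts()
    top = counts.max()
    k_star = int(min(k for k in counts.index if counts[k] == top))
    return k_star, votes


@dataclass(frozen=True)
class ClusterSolution:
    """Region labels, the merge tree, and the index-vote audit trail."""

    labels: np.ndarray
    k: int
    linkage: np.ndarray
    index_votes: pd.DataFrame | None
    region_ids: tuple[str, ...]

    def labels_by_region(self) -> dict[str, int]:
        return dict(zip(self.region_ids, (int(x) for x in self.labels)))

    def merge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.linkage[:, :3], columns=["left", "right", "height"]
        ).assign(step=lambda t: np.arange(1, len(t) + 1))


class WardNetworkClusterer(BaseEstimator, ClusterMixin):
    """Ward clustering over a precomputed dissimilarity, with optional
    automatic choice of the cluster count.

    Parameters
    ----------
    n_clusters : int or None, default None
        Fixed cluster count; None triggers the validity-index vote over
        ``k_range``.
    k_range : sequence of int, default 2..10
        Candidate counts for the vote.

    Attributes (after ``fit``)
    --------------------------
    labels_ : ndarray of int
    n_clusters_ : int
    linkage_ : scipy linkage matrix
    index_votes_ : DataFrame or None
    """

    def __init__(self, n_clusters: int | None = None, k_range=tuple(range(2, 11))):
        self.n_clusters = n_clusters
        self.k_range = k_range

    def fit(self, X: np.ndarray, y=None) -> "WardNetworkClusterer":
        d = _check_dissimilarity(np.asarray(X, dtype=float))
        self.linkage_ = ward_tree(d)
        if self.n_clusters is None:
            self.n_clusters_, self.index_votes_ = select_optimal_k(
                d, self.k_range, linkage=self.linkage_
            )
        else:
            self.n_clusters_ = int(self.n_clusters)
            self.index_votes_ = None
        self.labels_ = cut_tree_labels(self.linkage_, self.n_clusters_)
        return self

    def fit_predict(self, X: np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).labels_

    def solution(self, region_ids) -> ClusterSolution:
        return ClusterSolution(
            labels=self.labels_,
            k=self.n_clusters_,
            linkage=self.linkage_,
            index_votes=self.index_votes_,
            region_ids=tuple(region_ids),
        )
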