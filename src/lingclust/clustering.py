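"""K-means partitioning of participants in component-score space.

The number of clusters is chosen by the silhouette method: for each k in a
candidate range, the best-of-25 (by within-cluster sum of squares) k-means
solution is scored by its average silhouette width, and the k maximizing
that width wins (ties go to the smaller k).  Cluster ids are 1-based and
relabeled by decreasing cluster size so that cluster 1 is always the
largest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_samples

DEFAULT_N_INIT = 25
DEFAULT_K_RANGE = range(2, 9)


class ClusteringError(ValueError):
    """Invalid clustering request (k out of range, degenerate labels)."""


@dataclass(frozen=True)
class ClusterSolution:
    labels: np.ndarray               # 1..k per participant
    centroids: np.ndarray            # k × m, row j-1 is cluster j
    n_init: int
    seed: int
    inertia: float
    silhouette_per_point: np.ndarray
    avg_silhouette: float
    participant_ids: tuple[str, ...] = ()

    @property
    def k(self) -> int:
        return int(self.centroids.shape[0])

    def sizes(self) -> dict[int, int]:
        return {j: int(np.sum(self.labels == j)) for j in range(1, self.k + 1)}

    def labels_frame(self) -> pd.DataFrame:
        idx = list(self.participant_ids) if self.participant_ids else list(range(len(self.labels)))
        return pd.DataFrame(
            {"cluster": self.labels}, index=pd.Index(idx, name="participant_id")
        )


def _as_array(scores) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(scores, pd.DataFrame):
        return scores.to_numpy(dtype=float), tuple(str(i) for i in scores.index)
    return np.asarray(scores, dtype=float), ()


def silhouette(scores, labels) -> tuple[np.ndarray, float]:
    """Per-point silhouette widths s(i) = (b−a)/max(a,b) and their mean.

    ``a`` is the mean distance to the point's own cluster, ``b`` the
    smallest mean distance to another cluster; a singleton cluster's point
    gets s(i) = 0.  Requires at least two non-empty clusters.
    """
    X, _ = _as_array(scores)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ClusteringError("silhouette needs at least 2 clusters")
    per_point = silhouette_samples(X, y, metric="euclidean")
    return per_point, float(np.mean(per_point))


def kmeans_fit(scores, k: int, n_init: int = DEFAULT_N_INIT, seed: int = 0) -> ClusterSolution:
    """Best-of-``n_init`` Lloyd k-means by within-cluster sum of squares.

    Deterministic given the seed.  Cluster ids are reassigned by
    decreasing cluster size (ties by centroid first coordinate) so labels
    are stable across runs up to the data, not the initialization order.
    """
    X, ids = _as_array(scores)
    n = X.shape[0]
    if not 2 <= k <= n - 1:
        raise ClusteringError(f"k={k} outside [2, {n - 1}]")
    km = KMeans(
        n_clusters=k,
        n_init=n_init,
        random_state=seed,
        algorithm="lloyd",
        max_iter=300,
    ).fit(X)
    raw = km.labels_
    # relabel: largest cluster first; deterministic tie-break
    order = sorted(
        range(k),
        key=lambda j: (-int(np.sum(raw == j)), float(km.cluster_centers_[j, 0])),
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([remap[j] for j in raw])
    centroids = km.cluster_centers_[order]
    per_point, avg = silhouette(X, labels)
    return ClusterSolution(
        labels=labels,
        centroids=centroids,
        n_init=n_init,
        seed=seed,
        inertia=float(km.inertia_),
        silhouette_per_point=per_point,
        avg_silhouette=avg,
        participant_ids=ids,
    )


def select_k(
    scores,
    k_range=DEFAULT_K_RANGE,
    n_init: int = DEFAULT_N_INIT,
    seed: int = 0,
) -> tuple[ClusterSolution, pd.DataFrame]:
    """Pick k by maximum average silhouette width.

    Returns the winning solution plus the per-k table (columns k,
    avg_silhouette).  Ties break toward the smaller k.
    """
    X, _ = _as_array(scores)
    n = X.shape[0]
    ks = [k for k in k_range]
    if not ks or min(ks) < 2 or max(ks) > n - 1:
        raise ClusteringError(f"k_range {ks} outside [2, {n - 1}]")
    best: ClusterSolution | None = None
    rows = []
    for k in sorted(ks):
        sol = kmeans_fit(scores, k, n_init=n_init, seed=seed)
        rows.append({"k": k, "avg_silhouette": sol.avg_silhouette})
        if best is None or sol.avg_silhouette > best.avg_silhouette:
            best = sol  # strict '>' keeps the smaller k on ties
    return best, pd.DataFrame(rows)
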