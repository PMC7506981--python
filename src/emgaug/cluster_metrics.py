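"""Cluster-quality metrics for augmented feature spaces.

Two classical internal validity indices, computed with auditable
intermediates:

Silhouette Coefficient (higher is better, range [-1, 1]):

    SC = (1/N) * sum_i (b(i) - a(i)) / max{a(i), b(i)}

where a(i) is the mean distance from point i to the other points of its
own cluster and b(i) the smallest mean distance from i to the points of
any other cluster.  Points in singleton clusters score s(i) = 0.

Davies-Bouldin index (lower is better, positive):

    DB = (1/K) * sum_i max_{j != i} (sigma_i + sigma_j) / d(c_i, c_j)

with c_i the cluster centroid, sigma_i the mean distance of cluster-i
points to c_i, and d the Euclidean centroid distance.

Distances are Euclidean throughout.  Feature vectors can be anything —
in an augmentation study typically CNN features or raw flattened L x C
windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import ParameterError

__all__ = ["FeatureMatrix", "ClusterReport", "silhouette", "davies_bouldin", "evaluate"]


@dataclass(frozen=True)
class FeatureMatrix:
    """``(N, D)`` feature vectors with an integer cluster label per row."""

    vectors: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        vectors = np.atleast_2d(np.asarray(self.vectors, dtype=float))
        labels = np.asarray(self.labels)
        if vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D matrix")
        if labels.shape != (vectors.shape[0],):
            raise ValueError("labels must be a vector with one entry per row")
        if not np.all(np.isfinite(vectors)):
            raise ValueError("vectors contain non-finite values")
        object.__setattr__(self, "vectors", vectors)
        object.__setattr__(self, "labels", labels)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


@dataclass
class ClusterReport:
    """Metric values plus the per-point / per-cluster intermediates."""

    sc: float | None = None
    db: float | None = None
    per_point_s: np.ndarray | None = field(default=None, repr=False)
    centroids: dict = field(default_factory=dict, repr=False)
    dispersions: dict = field(default_factory=dict, repr=False)
    centroid_distances: dict = field(default_factory=dict, repr=False)

    def to_dict(self) -> dict:
        out: dict = {}
        if self.sc is not None:
            out["silhouette"] = float(self.sc)
        if self.db is not None:
            out["davies_bouldin"] = float(self.db)
            out["dispersions"] = {str(k): float(v) for k, v in self.dispersions.items()}
        return out


def _require_clusters(fm: FeatureMatrix, metric: str):
    if fm.n_clusters < 2:
        raise ParameterError(f"{metric} undefined for K=1 (single cluster)")


def silhouette(fm: FeatureMatrix) -> ClusterReport:
    """Silhouette Coefficient with per-point scores."""
    _require_clusters(fm, "silhouette")
    X, labels = fm.vectors, fm.labels
    uniq = np.unique(labels)
    dists = cdist(X, X)
    n = len(X)
    s = np.zeros(n)
    # Per-cluster summed distances let a(i) and b(i) come from one matrix.
    sums = np.stack([dists[:, labels == k].sum(axis=1) for k in uniq], axis=1)
    sizes = np.array([(labels == k).sum() for k in uniq])
    for i in range(n):
        ki = int(np.flatnonzero(uniq == labels[i])[0])
        if sizes[ki] == 1:
            s[i] = 0.0  # singleton convention
            continue
        a = sums[i, ki] / (sizes[ki] - 1)
        other = [sums[i, k] / sizes[k] for k in range(len(uniq)) if k != ki]
        b = min(other)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return ClusterReport(sc=float(np.mean(s)), per_point_s=s)


def davies_bouldin(fm: FeatureMatrix) -> ClusterReport:
    """Davies-Bouldin index with centroids, dispersions and distances."""
    _require_clusters(fm, "Davies-Bouldin")
    X, labels = fm.vectors, fm.labels
    uniq = np.unique(labels)
    centroids = {int(k): X[labels == k].mean(axis=0) for k in uniq}
    dispersions = {
        int(k): float(
            np.mean(np.linalg.norm(X[labels == k] - centroids[int(k)], axis=1))
        )
        for k in uniq
    }
    dmat: dict[tuple[int, int], float] = {}
    for i, ki in enumerate(uniq):
        for kj in uniq[i + 1 :]:
            d = float(np.linalg.norm(centroids[int(ki)] - centroids[int(kj)]))
            if d == 0.0:
                raise ParameterError(
                    f"coincident centroids for clusters {int(ki)} and {int(kj)}: "
                    "Davies-Bouldin ratio is undefined"
                )
            dmat[(int(ki), int(kj))] = dmat[(int(kj), int(ki))] = d
    ratios = []
    for ki in uniq:
        worst = max(
            (dispersions[int(ki)] + dispersions[int(kj)]) / dmat[(int(ki), int(kj))]
            for kj in uniq
            if kj != ki
        )
        ratios.append(worst)
    return ClusterReport(
        db=float(np.mean(ratios)),
        centroids=centroids,
        dispersions=dispersions,
        centroid_distances=dmat,
    )


def evaluate(fm: FeatureMatrix) -> ClusterReport:
    """Both metrics in one report."""
    sil = silhouette(fm)
    dbr = davies_bouldin(fm)
    return ClusterReport(
        sc=sil.sc,
        db=dbr.db,
        per_point_s=sil.per_point_s,
        centroids=dbr.centroids,
        dispersions=dbr.dispersions,
        centroid_distances=dbr.centroid_distances,
    )
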