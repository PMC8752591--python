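"""Cluster order parameter k for a self-driven collective.

The collective is clustered with k-means on the feature vectors
``[x, y, v_x, v_y]`` (position plus velocity components).  Each candidate
number of clusters ``k`` in ``2 .. floor(sqrt(n))`` is scored by the average
contour coefficient

    S_i = (b - a) / max(a, b),        S = mean_i S_i,

where ``a`` is the mean distance from sample i to the other members of its
own cluster and ``b`` the mean distance to the members of the nearest
foreign cluster; the nearest foreign cluster is the one minimizing the mean
*squared* distance to sample i.  The ``k`` maximizing ``S`` is the cluster
order parameter: a synchronized collective packs into few clusters (small
k), a noisy one fragments (large k).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist
from sklearn.cluster import KMeans

from .vicsek import ParticleConfiguration

__all__ = [
    "FeatureMatrix",
    "ClusteringResult",
    "KSearchResult",
    "build_features",
    "kmeans_partition",
    "contour_coefficients",
    "contour_coefficient",
    "average_contour",
    "optimal_k",
    "cluster_order_parameter",
]


# A FeatureMatrix is a plain (n, 4) float array with rows [x, y, v_x, v_y].
FeatureMatrix = np.ndarray


@dataclass
class ClusteringResult:
    labels: np.ndarray  # (n,) ints in [0, k)
    k: int
    score: float  # average contour coefficient S


@dataclass
class KSearchResult:
    per_k: dict  # candidate k -> average contour coefficient
    best_k: int
    k_max: int

    @property
    def best_score(self) -> float:
        return self.per_k[self.best_k]


def build_features(cfg: ParticleConfiguration, speed: float) -> FeatureMatrix:
    """Stack raw box coordinates with velocity components v*(cos, sin)(theta).

    No standardization: positions and velocities enter the Euclidean metric
    at their natural scales.
    """
    vx = speed * np.cos(cfg.angles)
    vy = speed * np.sin(cfg.angles)
    return np.column_stack([cfg.positions[:, 0], cfg.positions[:, 1], vx, vy])


def kmeans_partition(feat: FeatureMatrix, k: int, seed: int = 0, n_init: int = 10) -> np.ndarray:
    """k-means labels from k-means++ seeding with multiple restarts."""
    n = feat.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, n]; got k={k}, n={n}")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(feat)


def _cluster_mean_distances(dist: np.ndarray, labels: np.ndarray, n_clusters: int):
    """Mean plain and squared distances from every point to every cluster.

    Returns (mean_d, mean_d2, counts): (n, k) arrays where column c holds the
    mean over all members of cluster c (the point itself included when it
    belongs to c).
    """
    n = dist.shape[0]
    onehot = np.zeros((n, n_clusters))
    onehot[np.arange(n), labels] = 1.0
    counts = onehot.sum(axis=0)
    mean_d = (dist @ onehot) / counts
    mean_d2 = ((dist**2) @ onehot) / counts
    return mean_d, mean_d2, counts


def contour_coefficients(
    feat: FeatureMatrix, labels: np.ndarray, dist: np.ndarray | None = None
) -> np.ndarray:
    """Per-sample contour coefficients S_i for a partition.

    ``a`` excludes the sample itself; a singleton own-cluster yields S_i = 0.
    Nearest-foreign-cluster selection uses the mean squared distance, while
    ``b`` itself is the mean plain distance to that cluster.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("contour coefficients need at least 2 clusters")
    # compact label range [0, k)
    remap = {c: i for i, c in enumerate(uniq)}
    lab = np.array([remap[c] for c in labels])
    k = uniq.size
    n = feat.shape[0]
    if dist is None:
        dist = squareform(pdist(feat))
    mean_d, mean_d2, counts = _cluster_mean_distances(dist, lab, k)

    own = counts[lab]
    with np.errstate(invalid="ignore", divide="ignore"):
        # mean distance to *other* members of the own cluster
        a = mean_d[np.arange(n), lab] * own / np.maximum(own - 1, 1)
    # foreign-cluster selection by mean squared distance
    d2 = mean_d2.copy()
    d2[np.arange(n), lab] = np.inf
    nearest = np.argmin(d2, axis=1)
    b = mean_d[np.arange(n), nearest]

    denom = np.maximum(a, b)
    s = np.where(denom > 0, (b - a) / np.where(denom > 0, denom, 1.0), 0.0)
    s[own == 1] = 0.0  # a undefined for singletons
    return s


def contour_coefficient(feat: FeatureMatrix, labels: np.ndarray, i: int) -> float:
    """Contour coefficient of one sample."""
    return float(contour_coefficients(feat, labels)[i])


def average_contour(
    feat: FeatureMatrix, labels: np.ndarray, dist: np.ndarray | None = None
) -> float:
    """Average contour coefficient S, in [-1, 1]."""
    return float(contour_coefficients(feat, labels, dist=dist).mean())


def optimal_k(
    feat: FeatureMatrix,
    seed: int = 0,
    k_min: int = 2,
    k_max: int | None = None,
    n_init: int = 10,
) -> KSearchResult:
    """Search k in [k_min, floor(sqrt(n))] for the largest average contour S.

    Ties break toward the smaller k.  The pairwise distance matrix is
    computed once and shared by every candidate score.
    """
    n = feat.shape[0]
    if k_max is None:
        k_max = int(np.floor(np.sqrt(n)))
    if k_max < k_min:
        raise ValueError(f"empty search range: need n >= {k_min**2}, got n={n}")
    dist = squareform(pdist(feat))
    per_k = {}
    for k in range(k_min, k_max + 1):
        labels = kmeans_partition(feat, k, seed=seed, n_init=n_init)
        per_k[k] = average_contour(feat, labels, dist=dist)
    best_k = max(sorted(per_k), key=lambda k: per_k[k])  # ties -> smaller k
    return KSearchResult(per_k=per_k, best_k=best_k, k_max=k_max)


def cluster_order_parameter(
    cfg: ParticleConfiguration, speed: float, seed: int = 0, k_max: int | None = None
) -> int:
    """The cluster order parameter k of a configuration."""
    feat = build_features(cfg, speed)
    return optimal_k(feat, seed=seed, k_max=k_max).best_k
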