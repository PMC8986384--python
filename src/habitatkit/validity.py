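"""Per-tumour cluster-validity statistics of a habitat segmentation.

Five numbers summarize how the K habitats of one tumour sit in the 6-D
intensity space; together they form the tumour's analysis feature vector:

inertia
    within-cluster sum of squared Euclidean distances to the centroids
    (cohesion; same quantity Lloyd's algorithm minimizes),
Calinski-Harabasz index
    ``[B/(k-1)] / [W/(N-k)]`` with between-group scatter
    ``B = sum_j n_j ||c_j - c_bar||^2`` and within-group scatter ``W`` =
    inertia (df-normalized separation-to-cohesion ratio),
silhouette coefficient
    mean over samples of ``(b - a)/max(a, b)`` contrasting the mean
    intra-cluster distance ``a`` with the mean distance ``b`` to the nearest
    other cluster; in [-1, 1],
separation (SP)
    arithmetic mean of the Euclidean distances between the k(k-1)/2
    unordered centroid pairs,
Davies-Bouldin index
    mean over clusters of the worst-case ``(S_j + S_l)/d(c_j, c_l)`` with
    ``S_j`` the mean member-to-centroid distance.

Scaling the feature space by ``c > 0`` multiplies separation by ``c`` and
inertia by ``c^2`` while leaving CH, silhouette and DB unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .habitats import HabitatLabeling
from .preprocess import VoxelFeatureMatrix


@dataclass
class ValidityFeatures:
    """The five per-tumour statistics plus provenance.

    ``degenerate`` flags a zero within-cluster scatter, in which case
    ``calinski_harabasz`` is the +inf sentinel and the study must be
    excluded from modelling.
    """

    inertia: float
    calinski_harabasz: float
    silhouette: float
    separation: float
    davies_bouldin: float
    study_id: str = "study"
    k: int = 0
    seed: int = 0
    degenerate: bool = False

    def as_dict(self) -> dict:
        return {
            "study_id": self.study_id,
            "inertia": self.inertia,
            "calinski_harabasz": self.calinski_harabasz,
            "silhouette": self.silhouette,
            "separation": self.separation,
            "davies_bouldin": self.davies_bouldin,
            "k": self.k,
            "seed": self.seed,
            "degenerate": self.degenerate,
        }


FEATURE_COLUMNS = (
    "inertia",
    "calinski_harabasz",
    "silhouette",
    "separation",
    "davies_bouldin",
)


def _as_xy(
    features: VoxelFeatureMatrix | np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    X = features.features if isinstance(features, VoxelFeatureMatrix) else np.asarray(
        features, dtype=float
    )
    y = np.asarray(labels, dtype=int)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and labels are misaligned")
    return X, y


def _cluster_ids(y: np.ndarray) -> np.ndarray:
    ids = np.unique(y)
    if any(np.sum(y == j) == 0 for j in ids):  # unreachable via unique; guard
        raise ValueError("empty cluster")
    return ids


def inertia(
    features: VoxelFeatureMatrix | np.ndarray,
    labels: np.ndarray,
    centroids: np.ndarray,
) -> float:
    """Within-cluster sum of squared distances to the supplied centroids."""
    X, y = _as_xy(features, labels)
    centroids = np.asarray(centroids, dtype=float)
    ids = _cluster_ids(y)
    if len(ids) != centroids.shape[0]:
        raise ValueError(
            f"{centroids.shape[0]} centroids for {len(ids)} nonempty clusters"
        )
    total = 0.0
    for row, j in enumerate(sorted(ids)):
        diff = X[y == j] - centroids[row]
        total += float(np.sum(diff * diff))
    return total


def calinski_harabasz(
    features: VoxelFeatureMatrix | np.ndarray, labels: np.ndarray
) -> float:
    """Between/within scatter ratio normalized by degrees of freedom.

    Returns ``inf`` when the within-cluster scatter is exactly zero (perfectly
    tight clusters); callers should treat that as a degenerate sentinel.
    """
    X, y = _as_xy(features, labels)
    ids = _cluster_ids(y)
    n, k = X.shape[0], len(ids)
    if k < 2 or k > n - 1:
        raise ValueError(f"Calinski-Harabasz needs 2 <= k <= N-1, got k={k}, N={n}")
    grand = X.mean(axis=0)
    B = 0.0
    W = 0.0
    for j in ids:
        members = X[y == j]
        c = members.mean(axis=0)
        B += members.shape[0] * float(np.sum((c - grand) ** 2))
        W += float(np.sum((members - c) ** 2))
    # Exactly-zero within scatter, or scatter at float-rounding level relative
    # to the between scatter, is the degenerate perfectly-tight limit.
    if W <= 1e-12 * max(B, 1.0):
        return math.inf
    return (B / (k - 1)) / (W / (n - k))


def silhouette(
    features: VoxelFeatureMatrix | np.ndarray, labels: np.ndarray
) -> float:
    """Mean silhouette coefficient over all samples.

    ``a_i`` is the mean distance to same-cluster points (excluding self),
    ``b_i`` the smallest mean distance to another cluster; a singleton
    cluster contributes ``s_i = 0``, and so does the 0/0 case of coincident
    points.
    """
    X, y = _as_xy(features, labels)
    ids = _cluster_ids(y)
    n, k = X.shape[0], len(ids)
    if k < 2 or k > n - 1:
        raise ValueError(f"silhouette needs 2 <= k <= N-1, got k={k}, N={n}")
    D = cdist(X, X)
    masks = {j: (y == j) for j in ids}
    sizes = {j: int(masks[j].sum()) for j in ids}
    # Mean distance from each sample to each cluster.
    mean_to = np.column_stack([D[:, masks[j]].mean(axis=1) for j in ids])
    id_pos = {j: p for p, j in enumerate(ids)}
    s = np.zeros(n)
    for i in range(n):
        j = y[i]
        nj = sizes[j]
        if nj == 1:
            s[i] = 0.0
            continue
        a = mean_to[i, id_pos[j]] * nj / (nj - 1)  # exclude self-distance 0
        b = min(mean_to[i, id_pos[l]] for l in ids if l != j)
        denom = max(a, b)
        s[i] = 0.0 if denom == 0.0 else (b - a) / denom
    return float(s.mean())


def separation(centroids: np.ndarray) -> float:
    """Mean Euclidean distance over all unordered centroid pairs."""
    centroids = np.asarray(centroids, dtype=float)
    if centroids.ndim != 2 or centroids.shape[0] < 2:
        raise ValueError("separation needs at least 2 centroids")
    return float(pdist(centroids).mean())


def davies_bouldin(
    features: VoxelFeatureMatrix | np.ndarray, labels: np.ndarray
) -> float:
    """Mean over clusters of the worst (S_j + S_l) / d(c_j, c_l) ratio.

    A pair of coincident centroids with zero scatter contributes 0 (fully
    degenerate identical clusters are treated as perfectly tight).
    """
    X, y = _as_xy(features, labels)
    ids = _cluster_ids(y)
    n, k = X.shape[0], len(ids)
    if k < 2 or k > n - 1:
        raise ValueError(f"Davies-Bouldin needs 2 <= k <= N-1, got k={k}, N={n}")
    centroids = np.vstack([X[y == j].mean(axis=0) for j in ids])
    S = np.array(
        [float(np.linalg.norm(X[y == j] - centroids[p], axis=1).mean())
         for p, j in enumerate(ids)]
    )
    d = cdist(centroids, centroids)
    total = 0.0
    for p in range(k):
        worst = 0.0
        for q in range(k):
            if p == q:
                continue
            num = S[p] + S[q]
            if d[p, q] == 0.0:
                r = 0.0 if num == 0.0 else math.inf
            else:
                r = num / d[p, q]
            worst = max(worst, r)
        total += worst
    return total / k


def compute_all(
    features: VoxelFeatureMatrix | np.ndarray,
    labeling: HabitatLabeling,
    study_id: str | None = None,
) -> ValidityFeatures:
    """All five statistics for one tumour's labelling, with provenance."""
    X, y = _as_xy(features, labeling.labels)
    w = inertia(X, y, labeling.centroids)
    ch = calinski_harabasz(X, y)
    sil = silhouette(X, y)
    sep = separation(labeling.centroids)
    db = davies_bouldin(X, y)
    if study_id is None:
        study_id = getattr(features, "study_id", "study")
    return ValidityFeatures(
        inertia=w,
        calinski_harabasz=ch,
        silhouette=sil,
        separation=sep,
        davies_bouldin=db,
        study_id=study_id,
        k=labeling.k,
        seed=labeling.seed,
        degenerate=not math.isfinite(ch),
    )
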