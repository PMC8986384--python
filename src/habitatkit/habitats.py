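"""Habitat segmentation: k-means partition of the tumour ROI in feature space.

Each tumour's ROI voxels, described by their standardized 6-sequence
intensity vectors, are split into K (default 3) habitats by Lloyd's
algorithm with Euclidean distances:

1. choose K initial centres (k-means++ by default),
2. assign every voxel to the nearest centre (ties to the lowest centre index),
3. move each centre to the mean of its assigned voxels,
4. repeat 2-3 until the centre shift falls below ``tol`` or ``max_iter``.

The best of ``n_init`` restarts (by final within-cluster SSE) is kept.
An optional expectation-maximization diagnostic fits a spherical Gaussian
mixture to the final labelling and reports its log-likelihood without
altering any label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import kmeans_plusplus

from .preprocess import StudyBundle, VolumeGrid, VoxelFeatureMatrix

logger = logging.getLogger("habitatkit")


@dataclass
class HabitatLabeling:
    """Result of one k-means segmentation.

    ``labels`` are 1-based habitat indices aligned with the rows of the
    feature matrix that produced them; ``inertia_trace`` records the
    within-cluster SSE after every assignment step of the winning restart
    and is non-increasing.
    """

    labels: np.ndarray
    centroids: np.ndarray
    inertia_trace: np.ndarray
    n_iter: int
    seed: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        self.inertia_trace = np.asarray(self.inertia_trace, dtype=float)

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    @property
    def inertia(self) -> float:
        return float(self.inertia_trace[-1])


def _as_array(features: VoxelFeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(features, VoxelFeatureMatrix):
        return features.features
    return np.asarray(features, dtype=float)


def _init_centers(
    X: np.ndarray, k: int, rng: np.random.Generator, method: str
) -> np.ndarray:
    if method == "k-means++":
        centers, _ = kmeans_plusplus(
            X, n_clusters=k, random_state=int(rng.integers(2**31 - 1))
        )
        return np.asarray(centers, dtype=float)
    if method == "random":
        idx = rng.choice(X.shape[0], size=k, replace=False)
        return X[idx].astype(float)
    raise ValueError(f"unknown init method: {method!r}")


def _lloyd(
    X: np.ndarray, centers: np.ndarray, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, list[float], int]:
    """One Lloyd run. Returns (labels0based, centers, inertia trace, n_iter)."""
    n, _ = X.shape
    k = centers.shape[0]
    trace: list[float] = []
    labels = np.zeros(n, dtype=int)
    for it in range(1, max_iter + 1):
        d2 = cdist(X, centers, metric="sqeuclidean")
        labels = np.argmin(d2, axis=1)  # ties -> lowest centre index
        # Empty-cluster repair: reseed on the point farthest from its centroid.
        # Placing the centre on that point strictly decreases the SSE, so the
        # recorded trace stays monotone.
        for j in range(k):
            if not np.any(labels == j):
                member_d2 = d2[np.arange(n), labels]
                p = int(np.argmax(member_d2))
                centers[j] = X[p]
                d2[:, j] = np.sum((X - centers[j]) ** 2, axis=1)
                labels = np.argmin(d2, axis=1)
        trace.append(float(d2[np.arange(n), labels].sum()))
        new_centers = np.vstack([X[labels == j].mean(axis=0) for j in range(k)])
        shift = float(np.max(np.linalg.norm(new_centers - centers, axis=1)))
        centers = new_centers
        if shift < tol:
            break
    # Final assignment against the returned centres so the labelling is a
    # fixed point of step 2.
    d2 = cdist(X, centers, metric="sqeuclidean")
    labels = np.argmin(d2, axis=1)
    trace.append(float(d2[np.arange(n), labels].sum()))
    return labels, centers, trace, it


def kmeans_cluster(
    features: VoxelFeatureMatrix | np.ndarray,
    k: int = 3,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    n_init: int = 10,
    init: str = "k-means++",
) -> HabitatLabeling:
    """Segment feature rows into ``k`` clusters with restarted Lloyd k-means.

    Parameters
    ----------
    features
        ``N x d`` array or :class:`VoxelFeatureMatrix`.
    k
        Number of habitats (3 in the standard analysis).
    seed
        Master seed; each restart derives its own stream from it.
    tol
        Convergence threshold on the maximum centre displacement.
    n_init
        Number of independent restarts; the run with the lowest final
        within-cluster SSE wins.
    init
        ``"k-means++"`` (default) or ``"random"``.
    """
    X = _as_array(features)
    if X.ndim != 2:
        raise ValueError("features must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")

    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, list[float], int] | None = None
    for _ in range(n_init):
        centers0 = _init_centers(X, k, rng, init)
        run = _lloyd(X, centers0.copy(), max_iter, tol)
        if best is None or run[2][-1] < best[2][-1]:
            best = run
    labels, centers, trace, n_iter = best
    logger.debug(
        "kmeans k=%d n=%d seed=%d: inertia=%.6g after %d iterations",
        k, n, seed, trace[-1], n_iter,
    )
    return HabitatLabeling(
        labels=labels + 1,
        centroids=centers,
        inertia_trace=np.asarray(trace),
        n_iter=n_iter,
        seed=seed,
    )


def labels_to_volume(labeling: HabitatLabeling, study: StudyBundle) -> VolumeGrid:
    """Paint habitat indices back into the grid: 0 outside the ROI, 1..K inside.

    Round-trips with the feature-matrix back-mapping: re-extracting the ROI
    voxels of the output in C order reproduces ``labeling.labels`` exactly.
    """
    mask = study.mask_array
    voxel_index = np.argwhere(mask)
    if voxel_index.shape[0] != labeling.labels.shape[0]:
        raise ValueError(
            f"labeling has {labeling.labels.shape[0]} voxels but the study ROI "
            f"has {voxel_index.shape[0]}"
        )
    vol = np.zeros(mask.shape, dtype=int)
    vol[tuple(voxel_index.T)] = labeling.labels
    ref = study.roi_mask
    return VolumeGrid(vol, spacing=ref.spacing, origin=ref.origin)


def gmm_diagnostic(
    features: VoxelFeatureMatrix | np.ndarray, labeling: HabitatLabeling
) -> dict:
    """Expectation-maximization goodness diagnostic for a final labelling.

    Fits a spherical Gaussian mixture initialized at the k-means solution and
    reports its mean per-sample log-likelihood. Purely diagnostic: the habitat
    labels are never modified.
    """
    from sklearn.mixture import GaussianMixture

    X = _as_array(features)
    k = labeling.k
    gm = GaussianMixture(
        n_components=k,
        covariance_type="spherical",
        means_init=labeling.centroids,
        random_state=labeling.seed,
        max_iter=100,
    )
    gm.fit(X)
    return {
        "mean_log_likelihood": float(gm.score(X)),
        "converged": bool(gm.converged_),
        "k": k,
    }
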