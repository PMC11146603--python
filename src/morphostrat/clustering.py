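"""K-means clustering, stability (rand index) and separability (silhouette)
analysis, and data-driven selection of the cluster count K.

The cluster count is not known a priori, so K is swept over a grid (2..10 by
default) and judged on two axes:

* *reproducibility* — K-means is re-run many times with distinct seeds
  ("permutations"); the plain Rand index between runs measures how stable the
  discovered partition is;
* *separability* — the mean silhouette coefficient per K; K is chosen at the
  point where the silhouette score drops suddenly (elbow rule).

K-means here is Lloyd's algorithm with k-means++ seeding, fully determined by
an integer seed.  Empty clusters are re-seeded at the point farthest from its
centroid.  Euclidean distance throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "KMeansModel",
    "StabilityResult",
    "SilhouetteCurve",
    "ClusterSelection",
    "kmeans_fit",
    "assign",
    "rand_index",
    "stability_analysis",
    "silhouette_samples",
    "silhouette_curve",
    "select_k",
]


@dataclass
class KMeansModel:
    K: int
    centroids: np.ndarray
    inertia: float
    seed: int
    n_iterations: int
    labels_: np.ndarray | None = None
    inertia_history: tuple[float, ...] = ()

    def to_bytes(self) -> bytes:
        return self.centroids.tobytes()


def _kmeanspp(X: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((K, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for k in range(1, K):
        total = d2.sum()
        if total <= 0:
            centers[k] = X[rng.integers(n)]
            continue
        probs = d2 / total
        centers[k] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, ((X - centers[k]) ** 2).sum(axis=1))
    return centers


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int, tol: float):
    labels = np.zeros(X.shape[0], dtype=int)
    history = []
    for it in range(1, max_iter + 1):
        d2 = cdist(X, centers, "sqeuclidean")
        labels = d2.argmin(axis=1)          # ties -> lowest centroid index
        history.append(float(d2[np.arange(X.shape[0]), labels].sum()))
        new = centers.copy()
        for k in range(centers.shape[0]):
            members = labels == k
            if members.any():
                new[k] = X[members].mean(axis=0)
            else:
                # re-seed an empty cluster at the globally farthest point
                far = d2.min(axis=1).argmax()
                new[k] = X[far]
        shift = np.sqrt(((new - centers) ** 2).sum(axis=1)).max()
        centers = new
        if shift < tol:
            break
    d2 = cdist(X, centers, "sqeuclidean")
    labels = d2.argmin(axis=1)
    inertia = float(d2[np.arange(X.shape[0]), labels].sum())
    history.append(inertia)
    return centers, labels, inertia, it, tuple(history)


def kmeans_fit(X, K: int, seed: int = 0, n_init: int = 1,
               max_iter: int = 300, tol: float = 1e-6) -> KMeansModel:
    """Seeded k-means++ / Lloyd fit; best of ``n_init`` restarts by inertia."""
    X = _coerce(X)
    if X.shape[0] < K:
        raise ValueError(f"cannot fit K={K} clusters to {X.shape[0]} rows")
    best = None
    rng = np.random.default_rng(seed)
    for _ in range(n_init):
        centers0 = _kmeanspp(X, K, rng)
        fit = _lloyd(X, centers0, max_iter, tol)
        if best is None or fit[2] < best[2]:
            best = fit
    centers, labels, inertia, iters, history = best
    return KMeansModel(K=K, centroids=centers, inertia=inertia, seed=seed,
                       n_iterations=iters, labels_=labels, inertia_history=history)


def assign(model: KMeansModel, X) -> np.ndarray:
    """Nearest-centroid assignment; equidistant ties go to the lowest index."""
    X = _coerce(X)
    if X.shape[1] != model.centroids.shape[1]:
        raise ValueError("dimension mismatch between data and centroids")
    return cdist(X, model.centroids, "sqeuclidean").argmin(axis=1)


def _coerce(X) -> np.ndarray:
    from .reduction import ReducedFeatures
    from .encoding import FeatureMatrix
    if isinstance(X, ReducedFeatures):
        return X.Z
    if isinstance(X, FeatureMatrix):
        return X.X
    return np.asarray(X, dtype=float)


def rand_index(a: Sequence[int], b: Sequence[int]) -> float:
    """Plain Rand index: the fraction of sample pairs on which two labelings
    agree (both together or both apart).  Contingency-table formula, O(n)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("labelings must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("rand index needs at least 2 samples")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    nb = bi.max() + 1
    contingency = np.bincount(ai * nb + bi, minlength=(ai.max() + 1) * nb).astype(float)
    nij2 = (contingency * (contingency - 1) / 2).sum()
    rows = np.bincount(ai).astype(float)
    cols = np.bincount(bi).astype(float)
    ni2 = (rows * (rows - 1) / 2).sum()
    nj2 = (cols * (cols - 1) / 2).sum()
    total = n * (n - 1) / 2
    return float((total + 2 * nij2 - ni2 - nj2) / total)


@dataclass
class StabilityResult:
    table: pd.DataFrame              # K, mean_rand_index
    n_permutations: int
    pairing: str                     # consecutive | all_pairs

    def mean_ri(self, K: int) -> float:
        return float(self.table.set_index("K").loc[K, "mean_rand_index"])


def stability_analysis(X, K_grid: Sequence[int], n_permutations: int = 1000,
                       base_seed: int = 0, pairing: str = "consecutive",
                       n_init: int = 10) -> StabilityResult:
    """Mean Rand index between seeded K-means permutations, per K.

    Each permutation is an independently seeded fit with the conventional
    best-of-``n_init`` k-means++ restart policy (the sklearn default), so the
    statistic measures reproducibility of the discovered partition rather
    than the odds of a single bad initialization.  ``consecutive`` pairing
    compares permutation i with i+1 (n-1 pairs, preserving the n-fits
    budget); ``all_pairs`` compares every pair.
    """
    if n_permutations < 2:
        raise ValueError("need at least 2 permutations")
    if pairing not in ("consecutive", "all_pairs"):
        raise ValueError("pairing must be 'consecutive' or 'all_pairs'")
    X = _coerce(X)
    rows = []
    for K in K_grid:
        labelings = [
            kmeans_fit(X, K, seed=base_seed + 7919 * K + i, n_init=n_init).labels_
            for i in range(n_permutations)
        ]
        if pairing == "consecutive":
            ris = [rand_index(labelings[i], labelings[i + 1])
                   for i in range(n_permutations - 1)]
        else:
            ris = [rand_index(labelings[i], labelings[j])
                   for i in range(n_permutations)
                   for j in range(i + 1, n_permutations)]
        rows.append((K, float(np.mean(ris))))
    table = pd.DataFrame(rows, columns=["K", "mean_rand_index"])
    return StabilityResult(table=table, n_permutations=n_permutations, pairing=pairing)


def silhouette_samples(D: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-point silhouette s = (b - a) / max(a, b) from a distance matrix.

    ``a`` is the mean distance to other points of the own cluster, ``b`` the
    smallest mean distance to any other cluster.  Singletons score 0.
    """
    labels = np.asarray(labels)
    ks, inv = np.unique(labels, return_inverse=True)
    k = ks.size
    if k < 2:
        raise ValueError("silhouette is undefined for fewer than 2 clusters")
    onehot = np.zeros((labels.size, k))
    onehot[np.arange(labels.size), inv] = 1.0
    sums = D @ onehot                          # (n, k) summed distances
    counts = onehot.sum(axis=0)
    own = counts[inv]
    a = np.where(own > 1, sums[np.arange(labels.size), inv] / np.maximum(own - 1, 1), 0.0)
    means = sums / counts
    means[np.arange(labels.size), inv] = np.inf
    b = means.min(axis=1)
    denom = np.maximum(a, b)
    s = np.where(denom > 0, (b - a) / denom, 0.0)
    s[own == 1] = 0.0
    return s


@dataclass
class SilhouetteCurve:
    grid: tuple[int, ...]
    scores: np.ndarray
    metric: str = "euclidean"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"K": self.grid, "silhouette": self.scores})


def silhouette_curve(X, K_grid: Sequence[int], seed: int = 0, n_init: int = 5,
                     sample_cap: int = 5000) -> SilhouetteCurve:
    """Mean silhouette per K using the seeded k-means fit for each K.

    The pairwise distance matrix is computed once and reused across the grid;
    above ``sample_cap`` rows a seeded subsample is scored instead (the fit
    still uses all rows).
    """
    X = _coerce(X)
    grid = tuple(int(k) for k in K_grid)
    if X.shape[0] < max(grid) + 1:
        raise ValueError("need more rows than the largest K in the grid")
    rng = np.random.default_rng(seed)
    if X.shape[0] > sample_cap:
        sub = np.sort(rng.choice(X.shape[0], sample_cap, replace=False))
    else:
        sub = np.arange(X.shape[0])
    D = squareform(pdist(X[sub]))
    scores = []
    for K in grid:
        model = kmeans_fit(X, K, seed=seed + 31 * K, n_init=n_init)
        labels = model.labels_[sub]
        if np.unique(labels).size < 2:
            raise ValueError(f"K={K}: fewer than 2 clusters realized on the sample")
        scores.append(float(silhouette_samples(D, labels).mean()))
    return SilhouetteCurve(grid=grid, scores=np.asarray(scores))


@dataclass
class ClusterSelection:
    chosen_k: int
    method: str
    curve: SilhouetteCurve
    stability: StabilityResult | None = None
    warning: bool = False
    rationale: str = ""


def select_k(curve: SilhouetteCurve, method: str = "drop_from_peak",
             rel_tol: float = 0.10, manual_k: int | None = None,
             rationale: str = "", stability: StabilityResult | None = None) -> ClusterSelection:
    """Choose K from a silhouette curve.

    ``drop_from_peak`` (default): the largest K whose score is within a
    relative tolerance of the curve maximum — the last K before the score
    falls suddenly below the best achieved separability.  ``largest_drop``:
    the K immediately preceding the maximum forward decrease score(K) -
    score(K+1), ties toward smaller K.  ``manual_override`` records the given
    K and rationale.  A flat or monotonically rising curve yields the argmax
    with a warning flag.
    """
    grid = np.asarray(curve.grid)
    s = np.asarray(curve.scores, dtype=float)
    if grid.size < 3 and method != "manual_override":
        raise ValueError("selection needs a grid of at least 3 K values")

    if method == "manual_override":
        if manual_k is None or manual_k not in set(curve.grid):
            raise ValueError("manual_override needs a K inside the grid")
        return ClusterSelection(chosen_k=int(manual_k), method=method, curve=curve,
                                stability=stability, rationale=rationale)

    drops = s[:-1] - s[1:]
    flat = s.max() - s.min() < 1e-12
    monotone_up = (drops <= 0).all()
    if flat or monotone_up or s.max() <= 0:
        return ClusterSelection(chosen_k=int(grid[int(np.argmax(s))]), method=method,
                                curve=curve, stability=stability, warning=True,
                                rationale="no drop in curve; argmax fallback")

    if method == "largest_drop":
        chosen = int(grid[int(np.argmax(drops))])
    elif method == "drop_from_peak":
        peak = s.max()
        near = np.nonzero(s >= peak * (1.0 - rel_tol))[0]
        chosen = int(grid[int(near.max())])
    else:
        raise ValueError(f"unknown selection method {method!r}")
    return ClusterSelection(chosen_k=chosen, method=method, curve=curve,
                            stability=stability, rationale=rationale)
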