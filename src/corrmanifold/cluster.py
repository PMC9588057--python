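"""Partitioning algorithms on the correlation manifold and validity indices.

Three clustering algorithms — intrinsic Lloyd k-means (centroids are
Fréchet means), PAM-style k-medoids on a precomputed geodesic distance
matrix, and self-tuning spectral clustering — plus the silhouette score and
a geodesic Calinski-Harabasz index, both computed with the manifold
distance so that model selection over K needs no Euclidean embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .central import frechet_mean
from .geometry import GeometrySpec

__all__ = [
    "ClusterResult",
    "AffinityGraph",
    "kmeans",
    "kmedoids",
    "spectral",
    "affinity_graph",
    "silhouette",
    "ch_index",
    "CH_SENTINEL",
]

CH_SENTINEL = 1e15  # reported when within-cluster cohesion is exactly zero


@dataclass
class ClusterResult:
    """A partition of N observations into K clusters (labels in 1..K)."""

    labels: np.ndarray
    K: int
    centroids: np.ndarray | None = None  # matrices (k-means) or None
    medoid_indices: np.ndarray | None = None  # data indices (k-medoids)
    objective_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = np.bincount(self.labels, minlength=self.K + 1)[1:]
        if (counts == 0).any():
            raise ValueError("every cluster must be nonempty")


@dataclass
class AffinityGraph:
    """Self-tuning affinity graph and its normalized symmetric Laplacian."""

    S: np.ndarray
    sigma: np.ndarray
    degree: np.ndarray
    laplacian: np.ndarray


def _validate_dist(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.max(np.abs(D - D.T)) > 1e-8 or np.max(np.abs(np.diag(D))) > 1e-10:
        raise ValueError("distance matrix must be symmetric and hollow")
    if D.min() < -1e-12:
        raise ValueError("distance matrix must be nonnegative")
    return 0.5 * (D + D.T)


def _seed_centroid_indices(dist_fn, mats, K, rng):
    """Greedy distance-proportional seeding (k-means++ style) over data points."""
    N = mats.shape[0]
    idx = [int(rng.integers(N))]
    closest = None
    for _ in range(K - 1):
        d = dist_fn(mats[idx[-1]]) ** 2
        closest = d if closest is None else np.minimum(closest, d)
        w = closest.copy()
        w[idx] = 0.0
        if w.sum() <= 0:
            remaining = np.setdiff1d(np.arange(N), idx)
            idx.append(int(rng.choice(remaining)))
        else:
            idx.append(int(rng.choice(N, p=w / w.sum())))
    return np.array(idx)


def kmeans(
    data,
    K: int,
    spec: GeometrySpec | None = None,
    seed: int = 0,
    max_iter: int = 50,
    n_init: int = 4,
    mean_eps: float = 1e-7,
) -> ClusterResult:
    """Intrinsic Lloyd k-means: nearest-centroid assignment under the
    geodesic distance, centroid update by the Fréchet mean of each cluster.

    Centroids are seeded at data points by greedy distance-proportional
    sampling, with ``n_init`` seeded restarts keeping the partition of
    lowest within-cluster sum of squared geodesic distances.  Assignment
    ties are broken uniformly at random with the given seed; an emptied
    cluster is re-seeded with the observation farthest from its (stale)
    centroid.
    """
    spec = spec or GeometrySpec()
    mats = np.asarray(data, float)
    N = mats.shape[0]
    if not 1 <= K <= N:
        raise ValueError(f"K must be in [1, {N}], got {K}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_init)):
        start = _seed_centroid_indices(
            lambda c: geometry.dist_many(c, mats, spec), mats, K, rng
        )
        centroids = mats[start].copy()
        labels = np.zeros(N, dtype=int)
        trace: list[float] = []
        for _ in range(max_iter):
            D = geometry.cross_distances(mats, centroids, spec)  # N x K
            near = D <= D.min(axis=1, keepdims=True) + 1e-12
            new_labels = np.array(
                [rng.choice(np.nonzero(row)[0]) if row.sum() > 1
                 else int(np.argmax(row)) for row in near]
            )
            for k in range(K):  # repair empty clusters deterministically
                if not (new_labels == k).any():
                    far = int(np.argmax(D[:, k]))
                    new_labels[far] = k
            obj = float(np.sum(D[np.arange(N), new_labels] ** 2))
            trace.append(obj)
            if (new_labels == labels).all() and len(trace) > 1:
                break
            labels = new_labels
            for k in range(K):
                members = mats[labels == k]
                centroids[k] = frechet_mean(members, spec, eps=mean_eps).center
        if best is None or trace[-1] < best[0]:
            best = (trace[-1], labels, centroids, trace)
    _, labels, centroids, trace = best
    return ClusterResult(
        labels=labels + 1, K=K, centroids=centroids, objective_trace=trace
    )


def kmedoids(
    dist: np.ndarray, K: int, seed: int = 0, max_iter: int = 100
) -> ClusterResult:
    """PAM-style k-medoids on a precomputed distance matrix.

    Medoids are initialized by PAM's greedy BUILD phase (each new medoid
    maximizes the drop in total dissimilarity), then the algorithm
    alternates nearest-medoid assignment with replacing each medoid by the
    cluster member of minimal average dissimilarity; the total
    within-cluster dissimilarity is non-increasing.
    """
    D = _validate_dist(dist)
    N = D.shape[0]
    if not 1 <= K <= N:
        raise ValueError(f"K must be in [1, {N}], got {K}")
    rng = np.random.default_rng(seed)
    # BUILD: greedy deterministic initialization
    medoids = [int(np.argmin(D.sum(axis=1)))]
    closest = D[:, medoids[0]].copy()
    while len(medoids) < K:
        gains = np.sum(np.maximum(closest[None, :] - D, 0.0), axis=1)
        gains[medoids] = -np.inf
        nxt = int(np.argmax(gains))
        medoids.append(nxt)
        closest = np.minimum(closest, D[:, nxt])
    medoids = np.sort(medoids)
    trace: list[float] = []
    labels = np.zeros(N, dtype=int)
    for _ in range(max_iter):
        sub = D[:, medoids]  # N x K
        near = sub <= sub.min(axis=1, keepdims=True) + 1e-12
        labels = np.array(
            [rng.choice(np.nonzero(row)[0]) if row.sum() > 1 else int(np.argmax(row))
             for row in near]
        )
        labels[medoids] = np.arange(K)  # a medoid stays in its own cluster
        trace.append(float(np.sum(sub[np.arange(N), labels])))
        new_medoids = medoids.copy()
        for k in range(K):
            members = np.nonzero(labels == k)[0]
            within = D[np.ix_(members, members)].mean(axis=1)
            new_medoids[k] = members[int(np.argmin(within))]
        if (np.sort(new_medoids) == np.sort(medoids)).all():
            break
        medoids = new_medoids
    return ClusterResult(
        labels=labels + 1, K=K, medoid_indices=medoids, objective_trace=trace
    )


def affinity_graph(dist: np.ndarray, knn: int = 7) -> AffinityGraph:
    """Self-tuning affinity S_ij = exp(-d_ij^2 / (sigma_i sigma_j)).

    sigma_i is the distance from observation i to its knn-th nearest
    neighbor (self excluded).  Coincident points (zero local scale) take
    the limit values: affinity 1 at distance zero, 0 otherwise.  Distances
    below double-precision resolution of the geodesic computation are
    snapped to zero so duplicated observations behave as coincident.
    """
    D = _validate_dist(dist)
    N = D.shape[0]
    if not 1 <= knn < N:
        raise ValueError(f"knn must be in [1, {N - 1}], got {knn}")
    D = np.where(D < 1e-7 * (1.0 + D.max()), 0.0, D)
    offdiag = np.sort(D + np.diag(np.full(N, np.inf)), axis=1)
    sigma = offdiag[:, knn - 1]
    ss = np.outer(sigma, sigma)
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.exp(-(D**2) / ss)
    S[D == 0] = 1.0  # includes the diagonal
    S[(ss == 0) & (D > 0)] = 0.0
    degree = S.sum(axis=1)
    if (degree == 0).any():
        isolated = np.nonzero(degree == 0)[0]
        raise ValueError(f"affinity graph has isolated observations: {isolated}")
    dinv = 1.0 / np.sqrt(degree)
    L = dinv[:, None] * S * dinv[None, :]
    return AffinityGraph(S=S, sigma=sigma, degree=degree, laplacian=L)


def spectral(
    data=None,
    K: int = 2,
    knn: int = 7,
    spec: GeometrySpec | None = None,
    seed: int = 0,
    dist: np.ndarray | None = None,
) -> ClusterResult:
    """Normalized spectral clustering with a self-tuning affinity graph.

    Takes the K leading eigenvectors of L = D^{-1/2} S D^{-1/2} (the
    informative ones for this similarity-form Laplacian), row-normalizes
    them, and runs Euclidean k-means on the rows.
    """
    spec = spec or GeometrySpec()
    if dist is None:
        if data is None:
            raise ValueError("provide either data or a distance matrix")
        dist = geometry.pairwise_distances(np.asarray(data, float), spec)
    D = _validate_dist(dist)
    N = D.shape[0]
    if not 1 < K < N:
        raise ValueError(f"K must be in (1, {N}), got {K}")
    graph = affinity_graph(D, knn=knn)
    w, U = np.linalg.eigh(graph.laplacian)
    V = U[:, -K:]  # K largest eigenvalues
    norms = np.linalg.norm(V, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    V = V / norms
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=K, random_state=seed, n_init=10).fit(V)
    labels = km.labels_.astype(int)
    for k in range(K):
        if not (labels == k).any():
            labels[int(np.argmin(np.linalg.norm(V - km.cluster_centers_[k], axis=1)))] = k
    return ClusterResult(labels=labels + 1, K=K)


def silhouette(dist: np.ndarray, labels) -> tuple[float, np.ndarray]:
    """Silhouette score from a precomputed distance matrix.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)) with a(i) the mean within-cluster
    distance and b(i) the smallest mean distance to another cluster;
    singletons score 0 by convention.  Returns (global mean, per-point).
    """
    D = _validate_dist(dist)
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least two clusters")
    N = D.shape[0]
    s = np.zeros(N)
    for i in range(N):
        own = labels == labels[i]
        n_own = own.sum()
        b = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
        if n_own == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)  # exclude the zero self-distance
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(s.mean()), s


def ch_index(
    data, labels, spec: GeometrySpec | None = None, mean_eps: float = 1e-7
) -> float:
    """Calinski-Harabasz index with geodesic distances and Fréchet means.

    Ratio of between-cluster separation (sum of |S_k| d^2(mu_k, mu) over
    K-1) to within-cluster cohesion (sum of d^2(C_i, mu_k) over N-K);
    larger is better.  Perfectly coincident clusters have zero cohesion:
    the index is then reported as the sentinel ``CH_SENTINEL`` with a
    warning.
    """
    spec = spec or GeometrySpec()
    mats = np.asarray(data, float)
    labels = np.asarray(labels, dtype=int)
    uniq = np.unique(labels)
    K, N = len(uniq), mats.shape[0]
    if K < 2 or K >= N:
        raise ValueError(f"CH index requires 2 <= K < N, got K={K}, N={N}")
    mu = frechet_mean(mats, spec, eps=mean_eps).center
    sep = 0.0
    coh = 0.0
    for c in uniq:
        members = mats[labels == c]
        mu_k = frechet_mean(members, spec, eps=mean_eps).center
        sep += len(members) * geometry.geometry_dist(mu_k, mu, spec) ** 2
        coh += float(np.sum(geometry.dist_many(mu_k, members, spec) ** 2))
    if coh <= 1e-12 * max(1.0, sep):
        warnings.warn(
            "zero within-cluster cohesion; CH index degenerate, returning sentinel",
            RuntimeWarning, stacklevel=2,
        )
        return CH_SENTINEL
    return float((sep / (K - 1)) / (coh / (N - K)))
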