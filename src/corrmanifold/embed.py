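"""Low-dimensional Euclidean embeddings of correlation-matrix collections.

Classical MDS (strain minimization by eigendecomposition of the doubly
centered squared-distance matrix), metric MDS (stress minimization by the
SMACOF majorization algorithm, whose raw stress is non-increasing by
construction), and principal geodesic analysis (PCA of the log-mapped data
in the tangent space at the Fréchet mean, using coordinates orthonormal
under the affine-invariant inner product).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .central import frechet_mean
from .geometry import GeometrySpec

__all__ = ["EmbeddingResult", "PGAModel", "cmds", "mmds", "pga_fit", "pga_transform"]


@dataclass
class EmbeddingResult:
    """N x p coordinates plus method-specific diagnostics."""

    coords: np.ndarray
    method: str
    diagnostics: dict = field(default_factory=dict)
    converged: bool = True


@dataclass
class PGAModel:
    """Principal geodesic analysis model.

    ``basis`` holds the principal tangent directions at the Fréchet mean
    (as symmetric matrices, orthonormal under the affine-invariant inner
    product); mapped through the exponential they are the principal
    geodesics, an approximate basis near the mean.
    """

    mean: np.ndarray
    basis: np.ndarray  # k x n x n tangent matrices
    eigenvalues: np.ndarray  # all tangent-covariance eigenvalues, descending
    explained: np.ndarray  # fraction of tangent variance per kept component
    spec: GeometrySpec
    _coord_basis: np.ndarray = None  # k x dim orthonormal coordinate rows


def _validate_dist(D: np.ndarray) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.max(np.abs(D - D.T)) > 1e-8:
        raise ValueError("distance matrix must be symmetric")
    return 0.5 * (D + D.T)


def _double_center(D: np.ndarray) -> np.ndarray:
    N = D.shape[0]
    J = np.eye(N) - np.ones((N, N)) / N
    return -0.5 * J @ (D**2) @ J


def cmds(dist: np.ndarray, p: int) -> EmbeddingResult:
    """Classical (strain-minimizing) MDS.

    Coordinates are the top-p eigenvectors of the doubly centered matrix B
    scaled by the square root of their (positive) eigenvalues.  Negative
    eigenvalues — present whenever the distances are not Euclidean-
    realizable — are dropped and reported as a diagnostic, not clipped
    into coordinates.
    """
    D = _validate_dist(dist)
    N = D.shape[0]
    if not 1 <= p < N:
        raise ValueError(f"embedding dimension must be in [1, {N - 1}], got {p}")
    B = _double_center(D)
    B = 0.5 * (B + B.T)
    w, U = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, U = w[order], U[:, order]
    if w[0] <= 0:
        raise ValueError("degenerate embedding: no positive eigenvalue in B")
    keep = min(p, int(np.sum(w > 0)))
    coords = U[:, :keep] * np.sqrt(w[:keep])
    gram = coords @ coords.T
    denom = float(np.sum(B**2))
    strain = float(np.sqrt(np.sum((B - gram) ** 2) / denom)) if denom > 0 else 0.0
    return EmbeddingResult(
        coords=coords,
        method="cmds",
        diagnostics={
            "eigenvalues": w,
            "normalized_strain": strain,
            "negative_eigenvalue_mass": float(np.sum(np.abs(w[w < 0]))),
        },
    )


def _raw_stress(D: np.ndarray, X: np.ndarray) -> float:
    diff = X[:, None, :] - X[None, :, :]
    dX = np.linalg.norm(diff, axis=-1)
    return float(np.sum((D - dX) ** 2))  # over all i != j (diagonal is zero)


def mmds(
    dist: np.ndarray,
    p: int,
    max_iter: int = 500,
    tol: float = 1e-9,
    seed: int = 0,
    init: np.ndarray | None = None,
) -> EmbeddingResult:
    """Metric MDS by SMACOF stress majorization.

    Initialized from the classical-MDS solution (or a supplied
    configuration); each Guttman-transform update can only decrease the raw
    stress, and iteration stops when the relative stress change falls
    below ``tol``.
    """
    D = _validate_dist(dist)
    N = D.shape[0]
    if not 1 <= p < N:
        raise ValueError(f"embedding dimension must be in [1, {N - 1}], got {p}")
    if init is not None:
        X = np.array(init, dtype=float)
        if X.shape != (N, p):
            raise ValueError(f"init must have shape {(N, p)}")
    else:
        X0 = cmds(D, p).coords
        X = np.zeros((N, p))
        X[:, : X0.shape[1]] = X0
        if X0.shape[1] < p:  # pad degenerate directions with tiny jitter
            rng = np.random.default_rng(seed)
            X[:, X0.shape[1]:] = 1e-8 * rng.standard_normal((N, p - X0.shape[1]))
    X = X - X.mean(axis=0)  # stress is translation-invariant; the Guttman
    # transform returns centered configurations, so start centered
    stress = _raw_stress(D, X)
    trace = [stress]
    converged = False
    for _ in range(max_iter):
        diff = X[:, None, :] - X[None, :, :]
        dX = np.linalg.norm(diff, axis=-1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dX > 0, D / np.where(dX > 0, dX, 1.0), 0.0)
        Bmat = -ratio
        np.fill_diagonal(Bmat, 0.0)
        np.fill_diagonal(Bmat, -Bmat.sum(axis=1))
        X = (Bmat @ X) / N  # Guttman transform (all weights 1)
        new_stress = _raw_stress(D, X)
        trace.append(new_stress)
        if stress - new_stress <= tol * max(stress, 1e-300):
            converged = True
            stress = new_stress
            break
        stress = new_stress
    return EmbeddingResult(
        coords=X,
        method="mmds",
        diagnostics={"stress_trace": np.array(trace), "raw_stress": stress},
        converged=converged,
    )


def pga_fit(data, k: int, spec: GeometrySpec | None = None) -> PGAModel:
    """Fit principal geodesic analysis.

    Log-maps the data to the tangent space at the Fréchet mean, forms the
    empirical covariance of the metric-orthonormal tangent coordinates, and
    keeps the top-k eigenvectors.
    """
    spec = spec or GeometrySpec()
    mats = np.asarray(data, float)
    n = mats.shape[1]
    max_k = n * (n - 1) // 2 if spec.name == "correlation" else geometry.tangent_dim(n)
    if not 1 <= k <= max_k:
        raise ValueError(f"k must be in [1, {max_k}] for n={n}, got {k}")
    mean = frechet_mean(mats, spec).center
    logs, _ = geometry.log_many(mean, mats, spec)
    if spec.name == "euclidean":
        iu, ju = np.triu_indices(n)
        scale = np.where(iu == ju, 1.0, np.sqrt(2.0))
        coords = logs[:, iu, ju] * scale
    else:
        coords = np.array([geometry.tangent_to_coords(mean, L) for L in logs])
    cov = coords.T @ coords / coords.shape[0]
    w, U = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, U = np.maximum(w[order], 0.0), U[:, order]
    total = float(w.sum())
    explained = w[:k] / total if total > 0 else np.zeros(k)
    if spec.name == "euclidean":
        iu, ju = np.triu_indices(n)
        scale = np.where(iu == ju, 1.0, np.sqrt(2.0))
        basis = np.zeros((k, n, n))
        for j in range(k):
            V = np.zeros((n, n))
            V[iu, ju] = U[:, j] / scale
            basis[j] = V + V.T - np.diag(np.diag(V))
    else:
        basis = np.array(
            [geometry.coords_to_tangent(mean, U[:, j]) for j in range(k)]
        )
    return PGAModel(
        mean=mean, basis=basis, eigenvalues=w, explained=explained, spec=spec,
        _coord_basis=U[:, :k].T.copy(),
    )


def pga_transform(model: PGAModel, data) -> EmbeddingResult:
    """Project observations onto the principal geodesic directions.

    The Fréchet mean itself maps to the zero vector.
    """
    mats = np.asarray(data, float)
    spec = model.spec
    logs, _ = geometry.log_many(model.mean, mats, spec)
    n = mats.shape[1]
    if spec.name == "euclidean":
        iu, ju = np.triu_indices(n)
        scale = np.where(iu == ju, 1.0, np.sqrt(2.0))
        coords = logs[:, iu, ju] * scale
    else:
        coords = np.array(
            [geometry.tangent_to_coords(model.mean, L) for L in logs]
        )
    y = coords @ model._coord_basis.T
    return EmbeddingResult(
        coords=y,
        method="pga",
        diagnostics={
            "eigenvalues": model.eigenvalues,
            "explained_variance": model.explained,
        },
    )
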