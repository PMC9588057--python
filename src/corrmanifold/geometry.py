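"""Riemannian primitives for SPD and full-rank correlation matrices.

The space of full-rank correlation matrices (the elliptope) is treated as
the quotient of the SPD manifold, carrying the affine-invariant Riemannian
metric (AIRM), by the group of positive diagonal congruences ``S -> D S D``.
Distances between correlation matrices are therefore infima over the
diagonal fiber: ``d(C1, C2) = min_D d_AIRM(C1, D C2 D)``.  The minimizing
``D*`` also provides the horizontal-lift log map, and the exponential map is
realized by the ambient SPD exponential followed by the invariant submersion
(re-normalization to unit diagonal).

All matrix functions of symmetric matrices (sqrtm, logm, expm) are computed
by symmetric eigendecomposition.  A Euclidean (Frobenius) baseline and the
ambient AIRM geometry are exposed through the same interface so downstream
algorithms can switch geometry without code changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeometrySpec",
    "DiagonalScaling",
    "validate_spd",
    "validate_correlation",
    "submersion",
    "spd_dist",
    "spd_exp",
    "spd_log",
    "fiber_optimize",
    "corr_dist",
    "corr_exp",
    "corr_log",
    "pairwise_distances",
    "cross_distances",
    "log_many",
    "tangent_to_coords",
    "coords_to_tangent",
    "tangent_dim",
]

_SYM_TOL = 1e-10
_EIG_TOL = 1e-12
_NEAR_SINGULAR = 1e-10
_DIAG_TOL = 1e-12


class InvalidMatrixError(ValueError):
    """Raised when an input fails SPD / correlation-matrix validation."""


@dataclass(frozen=True)
class GeometrySpec:
    """Named geometry plus numerical budget for the fiber optimization.

    Parameters
    ----------
    name : {"correlation", "spd", "euclidean"}
        Which metric structure to use.
    tolerance : float
        Convergence tolerance (infinity-norm of the fiber-problem gradient).
    max_inner_iter : int
        Iteration budget for one fiber optimization.
    """

    name: str = "correlation"
    tolerance: float = 1e-9
    max_inner_iter: int = 100

    def __post_init__(self) -> None:
        if self.name not in ("correlation", "spd", "euclidean"):
            raise ValueError(f"unknown geometry name {self.name!r}")
        if self.tolerance <= 0 or self.max_inner_iter <= 0:
            raise ValueError("tolerance and max_inner_iter must be positive")


@dataclass
class DiagonalScaling:
    """A positive diagonal congruence ``S -> D S D``, stored as log entries."""

    log_entries: np.ndarray
    converged: bool = True
    n_iter: int = 0
    objective: float = 0.0  # squared AIRM distance at the optimum

    @property
    def matrix(self) -> np.ndarray:
        return np.diag(np.exp(self.log_entries))

    @property
    def entries(self) -> np.ndarray:
        return np.exp(self.log_entries)


# ---------------------------------------------------------------------------
# validation and symmetric matrix functions


def _as_sym(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    return 0.5 * (A + A.T)


def validate_spd(A: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Check symmetry and positive-definiteness; return a symmetrized copy."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise InvalidMatrixError(f"{name} is not square: shape {A.shape}")
    asym = np.max(np.abs(A - A.T))
    if asym > _SYM_TOL:
        raise InvalidMatrixError(f"{name} is not symmetric: |A - A^T| = {asym:.3e}")
    A = 0.5 * (A + A.T)
    lmin = np.linalg.eigvalsh(A)[0]
    if lmin <= _EIG_TOL:
        raise InvalidMatrixError(
            f"{name} is not positive definite: smallest eigenvalue {lmin:.3e}"
        )
    return A

def validate_correlation(C: np.ndarray, name: str = "matrix") -> np.ndarray:
    """Validate a full-rank correlation matrix (SPD, unit diagonal)."""
    C = validate_spd(C, name)
    dev = np.max(np.abs(np.diag(C) - 1.0))
    if dev > _DIAG_TOL:
        raise InvalidMatrixError(f"{name} diagonal deviates from 1 by {dev:.3e}")
    lmin = np.linalg.eigvalsh(C)[0]
    if lmin < _NEAR_SINGULAR:
        raise InvalidMatrixError(
            f"{name} is near-singular: smallest eigenvalue {lmin:.3e} < {_NEAR_SINGULAR:g}"
        )
    return C


def _eigh_fun(A: np.ndarray, fun) -> np.ndarray:
    """Apply a scalar function to a symmetric matrix via eigendecomposition."""
    w, U = np.linalg.eigh(_as_sym(A))
    return (U * fun(w)) @ U.T


def _spd_power(A: np.ndarray, p: float) -> np.ndarray:
    w, U = np.linalg.eigh(_as_sym(A))
    if w[0] <= 0:
        raise InvalidMatrixError(
            f"matrix power {p} of non-PD matrix (smallest eigenvalue {w[0]:.3e})"
        )
    return (U * w**p) @ U.T


def spd_sqrtm(A: np.ndarray) -> np.ndarray:
    return _spd_power(A, 0.5)


def spd_invsqrtm(A: np.ndarray) -> np.ndarray:
    return _spd_power(A, -0.5)


def spd_logm(A: np.ndarray) -> np.ndarray:
    w, U = np.linalg.eigh(_as_sym(A))
    if w[0] <= 0:
        raise InvalidMatrixError(
            f"matrix logarithm of non-PD matrix (smallest eigenvalue {w[0]:.3e})"
        )
    return (U * np.log(w)) @ U.T


def spd_expm(A: np.ndarray) -> np.ndarray:
    return _eigh_fun(A, np.exp)


# ---------------------------------------------------------------------------
# ambient SPD geometry (AIRM)


def submersion(S: np.ndarray) -> np.ndarray:
    """Project an SPD matrix to the correlation manifold.

    Computes ``diag(S)^{-1/2} S diag(S)^{-1/2}`` and then pins the diagonal
    to 1 bit-exactly, which is the canonical representative of the fiber
    through ``S``.
    """
    S = np.asarray(S, dtype=float)
    d = np.diag(S)
    if np.any(d <= 0):
        raise InvalidMatrixError(
            f"submersion of non-PD matrix: diagonal entry {d.min():.3e} <= 0"
        )
    lmin = np.linalg.eigvalsh(_as_sym(S))[0]
    if lmin <= 0:
        raise InvalidMatrixError(
            f"submersion of non-PD matrix: smallest eigenvalue {lmin:.3e}"
        )
    s = 1.0 / np.sqrt(d)
    C = _as_sym(S * np.outer(s, s))
    np.fill_diagonal(C, 1.0)
    return C


def spd_dist(A: np.ndarray, B: np.ndarray) -> float:
    """Affine-invariant distance ``||logm(A^{-1/2} B A^{-1/2})||_F``."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"dimension mismatch: {A.shape} vs {B.shape}")
    Ai = spd_invsqrtm(A)
    M = _as_sym(Ai @ B @ Ai)
    w = np.linalg.eigvalsh(M)
    if w[0] <= 0:
        raise InvalidMatrixError(
            f"second argument not PD relative to first (eigenvalue {w[0]:.3e})"
        )
    return float(np.sqrt(np.sum(np.log(w) ** 2)))


def spd_exp(base: np.ndarray, V: np.ndarray) -> np.ndarray:
    """AIRM exponential ``B^{1/2} expm(B^{-1/2} V B^{-1/2}) B^{1/2}``."""
    V = np.asarray(V, dtype=float)
    if np.max(np.abs(V - V.T)) > 1e-8 * max(1.0, np.max(np.abs(V))):
        raise ValueError("tangent vector is not symmetric")
    Bs = spd_sqrtm(base)
    Bi = spd_invsqrtm(base)
    inner = spd_expm(Bi @ _as_sym(V) @ Bi)
    return _as_sym(Bs @ inner @ Bs)


def spd_log(base: np.ndarray, X: np.ndarray) -> np.ndarray:
    """AIRM logarithm ``B^{1/2} logm(B^{-1/2} X B^{-1/2}) B^{1/2}``."""
    Bs = spd_sqrtm(base)
    Bi = spd_invsqrtm(base)
    inner = spd_logm(Bi @ np.asarray(X, float) @ Bi)
    return _as_sym(Bs @ inner @ Bs)


def airm_norm(base: np.ndarray, V: np.ndarray) -> float:
    """Norm of a tangent vector under the affine-invariant metric at base."""
    Bi = spd_invsqrtm(base)
    return float(np.linalg.norm(Bi @ _as_sym(V) @ Bi, "fro"))


# ---------------------------------------------------------------------------
# tangent coordinates (orthonormal under AIRM at the base point)


def tangent_dim(n: int) -> int:
    """Dimension of the symmetric-matrix tangent space at an n x n base."""
    return n * (n + 1) // 2


def _triu_indices(n: int):
    return np.triu_indices(n)


def tangent_to_coords(base: np.ndarray, V: np.ndarray) -> np.ndarray:
    """Orthonormal coordinates of a symmetric tangent vector at ``base``.

    Whitens by the base (``B^{-1/2} V B^{-1/2}``) and takes upper-triangle
    Frobenius coordinates with off-diagonals scaled by sqrt(2), so the
    Euclidean inner product of coordinates equals the affine-invariant inner
    product at the base point.
    """
    n = base.shape[0]
    Bi = spd_invsqrtm(base)
    W = _as_sym(Bi @ _as_sym(V) @ Bi)
    iu, ju = _triu_indices(n)
    scale = np.where(iu == ju, 1.0, np.sqrt(2.0))
    return W[iu, ju] * scale


def coords_to_tangent(base: np.ndarray, z: np.ndarray) -> np.ndarray:
    """Inverse of :func:`tangent_to_coords`."""
    n = base.shape[0]
    iu, ju = _triu_indices(n)
    scale = np.where(iu == ju, 1.0, np.sqrt(2.0))
    W = np.zeros((n, n))
    W[iu, ju] = np.asarray(z, float) / scale
    W = W + W.T - np.diag(np.diag(W))
    Bs = spd_sqrtm(base)
    return _as_sym(Bs @ W @ Bs)


# ---------------------------------------------------------------------------
# fiber optimization: min over positive diagonal D of d_AIRM(C1, D C2 D)^2
#
# Parametrized by x = log diag(D).  With A = C1^{-1/2} and
# M(x) = A D C2 D A, the objective is f(x) = ||logm M||_F^2 and the exact
# gradient is grad_k = 4 d_k (A G A D C2)_{kk}, where G = M^{-1} logm M
# (G commutes with M, so the trace of the Frechet derivative collapses).


def _batch_objective_grad(A, C2, X, want_grad=True):
    """Objective and gradient of the fiber problem over a stack of pairs.

    A : (P, n, n) inverse square roots of the first matrices
    C2 : (P, n, n) second matrices
    X : (P, n) log-diagonal iterates
    """
    with np.errstate(over="ignore", invalid="ignore"):
        d = np.exp(X)
        DC2D = d[:, :, None] * C2 * d[:, None, :]
        M = A @ DC2D @ A
    M = 0.5 * (M + np.swapaxes(M, -1, -2))
    finite = np.isfinite(M).all(axis=(-1, -2))
    if not finite.all():  # overflowed trial points: objective +inf
        M = M.copy()
        M[~finite] = np.eye(M.shape[-1])
    w, U = np.linalg.eigh(M)
    bad = (w[:, 0] <= 0) | ~finite
    wsafe = np.where(w > 0, w, 1.0)
    logw = np.log(wsafe)
    f = np.sum(logw**2, axis=-1)
    f[bad] = np.inf
    if not want_grad:
        return f, None
    G = (U * (logw / wsafe)[:, None, :]) @ np.swapaxes(U, -1, -2)
    H = A @ G @ A
    grad = 4.0 * d * np.einsum("pkj,pj,pjk->pk", H, d, C2)
    grad[bad] = np.nan
    return f, grad


def _fiber_batch(C1s, C2s, tol: float, max_iter: int):
    """Solve the fiber problem for a stack of (C1, C2) pairs.

    Newton iteration with exact gradient, central-difference Hessian and
    backtracking line search; falls back to steepest descent when the Newton
    direction is not a descent direction.

    Returns (X, f, converged, n_iter) with X the optimal log-diagonals and
    f the squared quotient distances.
    """
    C1s = np.asarray(C1s, float)
    C2s = np.asarray(C2s, float)
    P, n, _ = C1s.shape
    w, U = np.linalg.eigh(0.5 * (C1s + np.swapaxes(C1s, -1, -2)))
    if np.any(w[:, 0] <= 0):
        k = int(np.argmin(w[:, 0]))
        raise InvalidMatrixError(
            f"pair {k}: first matrix not PD (eigenvalue {w[k, 0]:.3e})"
        )
    A = (U * (w**-0.5)[:, None, :]) @ np.swapaxes(U, -1, -2)

    X = np.zeros((P, n))
    f, g = _batch_objective_grad(A, C2s, X)
    n_iter = np.zeros(P, dtype=int)
    h = 1e-5
    for it in range(max_iter):
        active = np.max(np.abs(g), axis=-1) >= tol
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        Aa, C2a, Xa = A[idx], C2s[idx], X[idx]
        ga, fa = g[idx], f[idx]
        # central-difference Hessian columns from the exact gradient
        Hs = np.empty((len(idx), n, n))
        for j in range(n):
            e = np.zeros(n)
            e[j] = h
            _, gp = _batch_objective_grad(Aa, C2a, Xa + e)
            _, gm = _batch_objective_grad(Aa, C2a, Xa - e)
            Hs[:, :, j] = (gp - gm) / (2 * h)
        Hs = 0.5 * (Hs + np.swapaxes(Hs, -1, -2))
        # Levenberg damping until the system solves and descends
        lam = np.zeros(len(idx))
        step = np.empty_like(Xa)
        eye = np.eye(n)
        pending = np.ones(len(idx), dtype=bool)
        for _ in range(40):
            if not pending.any():
                break
            p_idx = np.nonzero(pending)[0]
            Hd = Hs[p_idx] + lam[p_idx, None, None] * eye
            try:
                sol = np.linalg.solve(Hd, -ga[p_idx][..., None])[..., 0]
                ok = np.isfinite(sol).all(axis=-1)
            except np.linalg.LinAlgError:
                sol = np.full((len(p_idx), n), np.nan)
                ok = np.zeros(len(p_idx), dtype=bool)
            descent = ok & (np.einsum("pi,pi->p", sol, ga[p_idx]) < 0)
            step[p_idx[descent]] = sol[descent]
            pending[p_idx[descent]] = False
            lam[p_idx[~descent]] = np.maximum(1e-4, lam[p_idx[~descent]] * 10 + 1e-4)
        if pending.any():  # give up on Newton for these: steepest descent
            step[pending] = -ga[pending]
        # cap the step so exp(x) stays representable; positive rescaling
        # keeps it a descent direction and backtracking refines the length
        snorm = np.max(np.abs(step), axis=1)
        too_big = snorm > 20.0
        if too_big.any():
            step[too_big] *= (20.0 / snorm[too_big])[:, None]
        # backtracking line search (Armijo on f, with an absolute slack so
        # that predicted decreases below rounding noise still accept)
        t = np.ones(len(idx))
        gs = np.einsum("pi,pi->p", ga, step)
        slack = 1e-12 * np.maximum(1.0, np.abs(fa))
        Xn = Xa + t[:, None] * step
        fn, _ = _batch_objective_grad(Aa, C2a, Xn, want_grad=False)
        for _ in range(40):
            fail = ~(fn <= fa + 1e-4 * t * gs + slack)
            if not fail.any():
                break
            t[fail] *= 0.5
            Xn[fail] = Xa[fail] + t[fail, None] * step[fail]
            fsub, _ = _batch_objective_grad(Aa[fail], C2a[fail], Xn[fail], want_grad=False)
            fn[fail] = fsub
        accept = fn <= fa + slack
        Xa = np.where(accept[:, None], Xn, Xa)
        X[idx] = Xa
        fnew, gnew = _batch_objective_grad(Aa, C2a, Xa)
        f[idx], g[idx] = fnew, gnew
        n_iter[idx] += 1
    converged = np.max(np.abs(g), axis=-1) < tol
    return X, np.maximum(f, 0.0), converged, n_iter


def fiber_optimize(
    C1: np.ndarray, C2: np.ndarray, spec: GeometrySpec | None = None
) -> DiagonalScaling:
    """Optimal diagonal congruence aligning C2 with C1.

    Minimizes ``spd_dist(C1, D C2 D)`` over positive diagonal ``D``,
    starting from ``D = I`` (the canonical fiber representative).  Warns and
    returns the best iterate if the budget is exhausted.
    """
    spec = spec or GeometrySpec()
    C1 = np.asarray(C1, float)
    C2 = np.asarray(C2, float)
    if C1.shape != C2.shape:
        raise ValueError(f"dimension mismatch: {C1.shape} vs {C2.shape}")
    X, f, conv, iters = _fiber_batch(
        C1[None], C2[None], spec.tolerance, spec.max_inner_iter
    )
    if not conv[0]:
        warnings.warn(
            f"fiber optimization did not converge in {spec.max_inner_iter} "
            f"iterations (objective {f[0]:.3e}); returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )
    return DiagonalScaling(
        log_entries=X[0], converged=bool(conv[0]), n_iter=int(iters[0]),
        objective=float(f[0]),
    )


def corr_dist(
    C1: np.ndarray, C2: np.ndarray, spec: GeometrySpec | None = None
) -> float:
    """Quotient geodesic distance between two correlation matrices."""
    scal = fiber_optimize(C1, C2, spec)
    return float(np.sqrt(scal.objective))


def corr_log(
    base: np.ndarray, C: np.ndarray, spec: GeometrySpec | None = None
) -> np.ndarray:
    """Horizontal-lift logarithm: ``spd_log(base, D* C D*)``."""
    scal = fiber_optimize(base, C, spec)
    d = scal.entries
    return spd_log(base, d[:, None] * np.asarray(C, float) * d[None, :])


def corr_exp(
    base: np.ndarray, V: np.ndarray, spec: GeometrySpec | None = None
) -> np.ndarray:
    """Exponential map on the correlation manifold.

    The ambient AIRM exponential of the (horizontal) tangent vector is
    projected back to unit diagonal by the invariant submersion.
    """
    V = np.asarray(V, float)
    nrm = np.linalg.norm(V, "fro")
    if not np.isfinite(nrm) or nrm > 1e8:
        raise OverflowError(f"tangent vector norm {nrm:.3e} too large for exp map")
    return submersion(spd_exp(base, V))


# ---------------------------------------------------------------------------
# batched conveniences used by every downstream algorithm


def log_many(base, mats, spec: GeometrySpec | None = None):
    """Logs and distances from one base point to many targets.

    Returns (logs, dists): a (N, n, n) stack of horizontal-lift tangent
    vectors at ``base`` and the corresponding geodesic distances.  Dispatch
    on ``spec.name`` gives the AIRM and Euclidean analogues.
    """
    spec = spec or GeometrySpec()
    base = np.asarray(base, float)
    mats = np.asarray(mats, float)
    N = mats.shape[0]
    if spec.name == "euclidean":
        logs = mats - base[None]
        return logs, np.linalg.norm(logs.reshape(N, -1), axis=1)
    if spec.name == "spd":
        Bs, Bi = spd_sqrtm(base), spd_invsqrtm(base)
        inner = Bi[None] @ mats @ Bi[None]
        w, U = np.linalg.eigh(0.5 * (inner + np.swapaxes(inner, -1, -2)))
        if np.any(w[:, 0] <= 0):
            raise InvalidMatrixError("non-PD matrix in log_many")
        L = (U * np.log(w)[:, None, :]) @ np.swapaxes(U, -1, -2)
        logs = Bs[None] @ L @ Bs[None]
        logs = 0.5 * (logs + np.swapaxes(logs, -1, -2))
        return logs, np.sqrt(np.sum(np.log(w) ** 2, axis=-1))
    C1s = np.broadcast_to(base, mats.shape)
    X, f, conv, _ = _fiber_batch(C1s, mats, spec.tolerance, spec.max_inner_iter)
    if not conv.all():
        warnings.warn(
            f"{int((~conv).sum())}/{N} fiber optimizations hit the iteration "
            "budget in log_many", RuntimeWarning, stacklevel=2,
        )
    d = np.exp(X)
    aligned = d[:, :, None] * mats * d[:, None, :]
    Bs, Bi = spd_sqrtm(base), spd_invsqrtm(base)
    inner = Bi[None] @ aligned @ Bi[None]
    w, U = np.linalg.eigh(0.5 * (inner + np.swapaxes(inner, -1, -2)))
    L = (U * np.log(w)[:, None, :]) @ np.swapaxes(U, -1, -2)
    logs = Bs[None] @ L @ Bs[None]
    logs = 0.5 * (logs + np.swapaxes(logs, -1, -2))
    return logs, np.sqrt(np.maximum(f, 0.0))


def dist_many(base, mats, spec: GeometrySpec | None = None) -> np.ndarray:
    """Geodesic distances from one base point to many targets."""
    spec = spec or GeometrySpec()
    base = np.asarray(base, float)
    mats = np.asarray(mats, float)
    if spec.name == "euclidean":
        return np.linalg.norm((mats - base[None]).reshape(mats.shape[0], -1), axis=1)
    if spec.name == "spd":
        Bi = spd_invsqrtm(base)
        inner = Bi[None] @ mats @ Bi[None]
        w = np.linalg.eigvalsh(0.5 * (inner + np.swapaxes(inner, -1, -2)))
        if np.any(w[:, 0] <= 0):
            raise InvalidMatrixError("non-PD matrix in dist_many")
        return np.sqrt(np.sum(np.log(w) ** 2, axis=-1))
    C1s = np.broadcast_to(base, mats.shape)
    _, f, conv, _ = _fiber_batch(C1s, mats, spec.tolerance, spec.max_inner_iter)
    if not conv.all():
        warnings.warn("fiber optimization budget hit in dist_many",
                      RuntimeWarning, stacklevel=2)
    return np.sqrt(np.maximum(f, 0.0))


def cross_distances(xs, ys, spec: GeometrySpec | None = None) -> np.ndarray:
    """len(xs) x len(ys) matrix of geodesic distances between two lists."""
    spec = spec or GeometrySpec()
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    m, k = xs.shape[0], ys.shape[0]
    if spec.name == "euclidean":
        diff = xs[:, None] - ys[None, :]
        return np.linalg.norm(diff.reshape(m, k, -1), axis=-1)
    ii, jj = np.meshgrid(np.arange(m), np.arange(k), indexing="ij")
    C1s = xs[ii.ravel()]
    C2s = ys[jj.ravel()]
    if spec.name == "spd":
        return _spd_pair_dists(C1s, C2s).reshape(m, k)
    _, f, conv, _ = _fiber_batch(C1s, C2s, spec.tolerance, spec.max_inner_iter)
    if not conv.all():
        warnings.warn("fiber optimization budget hit in cross_distances",
                      RuntimeWarning, stacklevel=2)
    return np.sqrt(np.maximum(f, 0.0)).reshape(m, k)


def _spd_pair_dists(C1s, C2s):
    w1, U1 = np.linalg.eigh(0.5 * (C1s + np.swapaxes(C1s, -1, -2)))
    A = (U1 * (w1**-0.5)[:, None, :]) @ np.swapaxes(U1, -1, -2)
    M = A @ C2s @ A
    w = np.linalg.eigvalsh(0.5 * (M + np.swapaxes(M, -1, -2)))
    return np.sqrt(np.sum(np.log(w) ** 2, axis=-1))


def pairwise_distances(data, spec: GeometrySpec | None = None) -> np.ndarray:
    """Symmetric hollow matrix of pairwise distances under the named geometry.

    Each unordered pair is solved once; for the correlation geometry all
    pairs are stacked and solved in one batched Newton iteration.
    """
    spec = spec or GeometrySpec()
    try:
        mats = np.asarray(data, float)
    except ValueError as exc:
        raise ValueError(
            f"data must be a stack of square matrices of equal size: {exc}"
        ) from None
    if mats.ndim != 3 or mats.shape[1] != mats.shape[2]:
        raise ValueError("data must be a stack of square matrices of equal size")
    N = mats.shape[0]
    D = np.zeros((N, N))
    if N == 1:
        return D
    iu, ju = np.triu_indices(N, k=1)
    if spec.name == "euclidean":
        flat = mats.reshape(N, -1)
        diff = flat[iu] - flat[ju]
        vals = np.linalg.norm(diff, axis=1)
    elif spec.name == "spd":
        vals = _spd_pair_dists(mats[iu], mats[ju])
    else:
        _, f, conv, _ = _fiber_batch(
            mats[iu], mats[ju], spec.tolerance, spec.max_inner_iter
        )
        if not conv.all():
            warnings.warn(
                f"{int((~conv).sum())}/{len(iu)} fiber optimizations hit the "
                "iteration budget in pairwise_distances",
                RuntimeWarning, stacklevel=2,
            )
        vals = np.sqrt(np.maximum(f, 0.0))
    D[iu, ju] = vals
    D[ju, iu] = vals
    return D


def geometry_dist(A, B, spec: GeometrySpec | None = None) -> float:
    """Distance between two matrices under the named geometry."""
    spec = spec or GeometrySpec()
    if spec.name == "euclidean":
        return float(np.linalg.norm(np.asarray(A, float) - np.asarray(B, float), "fro"))
    if spec.name == "spd":
        return spd_dist(A, B)
    return corr_dist(A, B, spec)


def geometry_exp(base, V, spec: GeometrySpec | None = None):
    """Exponential map under the named geometry."""
    spec = spec or GeometrySpec()
    if spec.name == "euclidean":
        return np.asarray(base, float) + np.asarray(V, float)
    if spec.name == "spd":
        return spd_exp(base, V)
    return corr_exp(base, V, spec)
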