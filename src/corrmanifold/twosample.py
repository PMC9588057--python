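"""Permutation two-sample tests for distributions of correlation matrices.

Two statistics are offered, both functions of the pooled matrix of pairwise
geodesic distances, so that a permutation test only shuffles labels and
never re-solves the underlying fiber optimizations:

* the Biswas-Ghosh interpoint-distance statistic
  ``T = (mFF - mFG)^2 + (mGG - mFG)^2`` built from the mean within-first,
  within-second and between-sample distances, and
* the order-2 Wasserstein distance between the two empirical measures with
  the geodesic distance as ground cost, solved by exact discrete optimal
  transport (assignment problem for equal sample sizes, a small linear
  program otherwise).

p-values use the add-one convention ``(1 + #{T_b >= T_obs}) / (B + 1)``,
which never returns zero and counts ties conservatively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment, linprog

from . import geometry
from .geometry import GeometrySpec

__all__ = ["TestResult", "TwoSample", "bg_statistic", "wass_statistic", "permutation_test"]


@dataclass
class TestResult:
    statistic: float
    pvalue: float
    n_perm: int
    method: str
    seed: int


class TwoSample:
    """Two samples of correlation matrices with a shared pooled distance matrix.

    Parameters
    ----------
    X, Y : stacks of matrices (m and n observations of equal dimension).
    spec : geometry under which pairwise distances are computed.
    pooled_dist : optional precomputed (m+n) x (m+n) distance matrix of the
        concatenated sample, in X-then-Y order.
    """

    def __init__(self, X, Y, spec: GeometrySpec | None = None,
                 pooled_dist: np.ndarray | None = None):
        X = np.asarray(X, float)
        Y = np.asarray(Y, float)
        if X.ndim != 3 or Y.ndim != 3 or X.shape[1:] != Y.shape[1:]:
            raise ValueError("X and Y must be matrix stacks of equal dimension")
        self.X, self.Y = X, Y
        self.m, self.n = X.shape[0], Y.shape[0]
        self.spec = spec or GeometrySpec()
        if pooled_dist is None:
            pooled = np.concatenate([X, Y], axis=0)
            pooled_dist = geometry.pairwise_distances(pooled, self.spec)
        pooled_dist = np.asarray(pooled_dist, float)
        if pooled_dist.shape != (self.m + self.n,) * 2:
            raise ValueError("pooled distance matrix has wrong shape")
        self.pooled_dist = pooled_dist


def _bg_from_dist(D: np.ndarray, idx_x: np.ndarray, idx_y: np.ndarray) -> float:
    m, n = len(idx_x), len(idx_y)
    if m < 2 or n < 2:
        raise ValueError("Biswas-Ghosh statistic needs at least 2 per sample")
    DXX = D[np.ix_(idx_x, idx_x)]
    DYY = D[np.ix_(idx_y, idx_y)]
    DXY = D[np.ix_(idx_x, idx_y)]
    mFF = DXX[np.triu_indices(m, 1)].mean()
    mGG = DYY[np.triu_indices(n, 1)].mean()
    mFG = DXY.mean()
    return float((mFF - mFG) ** 2 + (mGG - mFG) ** 2)


def _wass_from_dist(D, idx_x, idx_y, order: int = 2) -> float:
    m, n = len(idx_x), len(idx_y)
    cost = D[np.ix_(idx_x, idx_y)] ** order
    if m == n:  # uniform marginals of equal size: optimal plan is a matching
        ri, ci = linear_sum_assignment(cost)
        total = cost[ri, ci].sum() / m
    else:
        # exact OT between uniform measures via the transport LP
        c = cost.ravel()
        A_eq = np.zeros((m + n, m * n))
        for i in range(m):
            A_eq[i, i * n:(i + 1) * n] = 1.0
        for j in range(n):
            A_eq[m + j, j::n] = 1.0
        b_eq = np.concatenate([np.full(m, 1.0 / m), np.full(n, 1.0 / n)])
        res = linprog(c, A_eq=A_eq[:-1], b_eq=b_eq[:-1], bounds=(0, None),
                      method="highs")
        if not res.success:
            raise RuntimeError(
                "transport LP failed: "
                f"{res.message}; cost matrix range [{cost.min():.3e}, {cost.max():.3e}]"
            )
        total = float(res.fun)
    return float(max(total, 0.0) ** (1.0 / order))


def bg_statistic(ts: TwoSample) -> float:
    """Biswas-Ghosh interpoint-distance statistic of the two samples."""
    idx = np.arange(ts.m + ts.n)
    return _bg_from_dist(ts.pooled_dist, idx[: ts.m], idx[ts.m:])


def wass_statistic(ts: TwoSample, order: int = 2) -> float:
    """Order-``order`` Wasserstein distance between the empirical measures."""
    idx = np.arange(ts.m + ts.n)
    return _wass_from_dist(ts.pooled_dist, idx[: ts.m], idx[ts.m:], order)


def permutation_test(
    ts: TwoSample,
    method: str = "bg",
    B: int = 1000,
    seed: int = 0,
) -> TestResult:
    """Monte-Carlo permutation test of equal distributions.

    Labels are reassigned uniformly at random over the pooled sample B
    times (sampling from the permutation group with replacement), reusing
    the precomputed pooled distance matrix.
    """
    if B < 1:
        raise ValueError("B must be at least 1")
    if method not in ("bg", "wass"):
        raise ValueError(f"method must be 'bg' or 'wass', got {method!r}")
    stat = _bg_from_dist if method == "bg" else _wass_from_dist
    N = ts.m + ts.n
    idx = np.arange(N)
    t_obs = stat(ts.pooled_dist, idx[: ts.m], idx[ts.m:])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(B):
        perm = rng.permutation(N)
        t_b = stat(ts.pooled_dist, perm[: ts.m], perm[ts.m:])
        if t_b >= t_obs:
            count += 1
    pvalue = (1 + count) / (B + 1)
    return TestResult(
        statistic=float(t_obs), pvalue=float(pvalue), n_perm=B,
        method=method, seed=seed,
    )
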