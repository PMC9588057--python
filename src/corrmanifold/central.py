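"""Measures of central tendency and dispersion on the correlation manifold.

The sample Fréchet mean (p=2) and median (p=1) minimize the average
p-th-power geodesic distance to the data.  Both are computed by intrinsic
fixed-point iterations: a Karcher gradient step for the mean and a
Riemannian Weiszfeld update for the median, each with step halving on cost
increase so the objective is monotone non-increasing.  The attained average
distance is the sample variation V_p.

Under the correlation geometry every iterate is itself a valid correlation
matrix — the point of working in the quotient geometry rather than the
ambient SPD manifold, whose Fréchet mean of correlation matrices is in
general not a correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .geometry import GeometrySpec

__all__ = ["CenterResult", "frechet_mean", "frechet_median", "variation"]


@dataclass
class CenterResult:
    """Outcome of a Fréchet mean/median computation."""

    center: np.ndarray
    p: int
    variation: float
    iterations: int
    increment_trace: list[float] = field(default_factory=list)
    cost_trace: list[float] = field(default_factory=list)
    converged: bool = True


def _initial_center(mats: np.ndarray, spec: GeometrySpec) -> np.ndarray:
    """Euclidean average, pushed into the manifold for the quotient geometry."""
    avg = mats.mean(axis=0)
    if spec.name == "correlation":
        return geometry.submersion(avg)
    return avg  # average of SPD matrices is SPD; Euclidean needs nothing


def _check_data(data) -> np.ndarray:
    mats = np.asarray(data, dtype=float)
    if mats.ndim != 3 or mats.shape[0] == 0:
        raise ValueError("data must be a nonempty stack of square matrices")
    if mats.shape[1] != mats.shape[2]:
        raise ValueError("matrices must be square")
    return mats


def frechet_mean(
    data,
    spec: GeometrySpec | None = None,
    eps: float = 1e-8,
    max_iter: int = 200,
) -> CenterResult:
    """Sample Fréchet mean under the named geometry.

    Karcher iteration: pull the data to the tangent space at the current
    iterate, average, and follow the exponential map along the mean tangent
    (unit step, halved whenever the cost f = mean squared distance
    increases).  Stops when the Frobenius increment between successive
    iterates falls below ``eps`` — a small increment means the averaged
    gradient is already tiny.
    """
    spec = spec or GeometrySpec()
    mats = _check_data(data)
    mu = _initial_center(mats, spec)
    logs, dists = geometry.log_many(mu, mats, spec)
    cost = float(np.mean(dists**2))
    incs: list[float] = []
    costs: list[float] = [cost]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        T = logs.mean(axis=0)
        tau = 1.0
        for _ in range(30):
            cand = geometry.geometry_exp(mu, tau * T, spec)
            cand_logs, cand_dists = geometry.log_many(cand, mats, spec)
            cand_cost = float(np.mean(cand_dists**2))
            if cand_cost <= cost + 1e-14 * max(1.0, cost):
                break
            tau *= 0.5
        inc = float(np.linalg.norm(cand - mu, "fro"))
        mu, logs, dists, cost = cand, cand_logs, cand_dists, cand_cost
        incs.append(inc)
        costs.append(cost)
        if inc < eps:
            converged = True
            break
    return CenterResult(
        center=mu, p=2, variation=cost, iterations=it,
        increment_trace=incs, cost_trace=costs, converged=converged,
    )


def frechet_median(
    data,
    spec: GeometrySpec | None = None,
    eps: float = 1e-8,
    max_iter: int = 200,
    weight_floor: float = 1e-12,
) -> CenterResult:
    """Sample Fréchet median by the Riemannian Weiszfeld algorithm.

    The update averages the log-mapped data with weights 1/d(mu, C_i); a
    floor of ``weight_floor`` is added to every distance so an iterate
    coinciding with a data point never produces a singular weight.  The
    step is halved whenever the cost g = mean distance would increase, so
    the cost trace is non-increasing.
    """
    spec = spec or GeometrySpec()
    mats = _check_data(data)
    mu = _initial_center(mats, spec)
    logs, dists = geometry.log_many(mu, mats, spec)
    cost = float(np.mean(dists))
    incs: list[float] = []
    costs: list[float] = [cost]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = 1.0 / (dists + weight_floor)
        W = np.tensordot(w, logs, axes=(0, 0)) / w.sum()
        tau = 1.0
        for _ in range(30):
            cand = geometry.geometry_exp(mu, tau * W, spec)
            cand_logs, cand_dists = geometry.log_many(cand, mats, spec)
            cand_cost = float(np.mean(cand_dists))
            if cand_cost <= cost + 1e-14 * max(1.0, cost):
                break
            tau *= 0.5
        inc = float(np.linalg.norm(cand - mu, "fro"))
        mu, logs, dists, cost = cand, cand_logs, cand_dists, cand_cost
        incs.append(inc)
        costs.append(cost)
        if inc < eps:
            converged = True
            break
    return CenterResult(
        center=mu, p=1, variation=cost, iterations=it,
        increment_trace=incs, cost_trace=costs, converged=converged,
    )


def variation(data, center, p: int, spec: GeometrySpec | None = None) -> float:
    """Sample variation V_p = mean of d^p(center, C_i) — the manifold
    analogue of the variance (p=2) or mean absolute deviation (p=1)."""
    if p not in (1, 2):
        raise ValueError(f"p must be 1 or 2, got {p}")
    spec = spec or GeometrySpec()
    mats = _check_data(data)
    d = geometry.dist_many(np.asarray(center, float), mats, spec)
    return float(np.mean(d**p))
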