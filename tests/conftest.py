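"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from corrmanifold import geometry, synthetic


def rand_corr(n: int, seed: int) -> np.ndarray:
    """Random full-rank correlation matrix (submersed Wishart)."""
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((n, 2 * n))
    return geometry.submersion(G @ G.T / (2 * n))


def airm_dist_2x2_grid(C1, C2, lo=0.2, hi=5.0, step=1e-3):
    """Brute-force oracle for the 2x2 quotient distance.

    Exhaustive grid search over positive diagonal D = diag(d1, d2) of
    d_AIRM(C1, D C2 D), using the closed-form eigenvalues of the 2x2
    matrix C1^{-1} (D C2 D) (trace/determinant), fully vectorized.
    Independent of the package's fiber optimizer.
    """
    grid = np.arange(lo, hi + step / 2, step)
    a, b = C1[0, 0], C1[0, 1]
    det1 = a * C1[1, 1] - b * b
    inv = np.array([[C1[1, 1], -b], [-b, a]]) / det1
    p, q, r = C2[0, 0], C2[0, 1], C2[1, 1]
    # determinant of C1^{-1} D C2 D factorizes; only the trace needs the grid
    logdet = np.log((p * r - q * q) / det1)
    best_val, best_d = np.inf, (1.0, 1.0)
    for start in range(0, len(grid), 256):  # chunk rows to bound memory
        d1 = grid[start:start + 256][:, None]
        d2 = grid[None, :]
        tr = (
            inv[0, 0] * d1 * d1 * p
            + 2 * inv[0, 1] * d1 * d2 * q
            + inv[1, 1] * d2 * d2 * r
        )
        det = np.exp(logdet + 2 * (np.log(d1) + np.log(d2)))
        disc = np.sqrt(np.maximum(tr * tr - 4 * det, 0.0))
        val = np.log((tr + disc) / 2) ** 2 + np.log((tr - disc) / 2) ** 2
        k = np.unravel_index(np.argmin(val), val.shape)
        if val[k] < best_val:
            best_val = float(val[k])
            best_d = (float(grid[start + k[0]]), float(grid[k[1]]))
    return float(np.sqrt(best_val)), best_d


def corr2(rho: float) -> np.ndarray:
    return np.array([[1.0, rho], [rho, 1.0]])


@pytest.fixture(scope="session")
def separated_models():
    """Three 5x5 model correlation matrices at pairwise geodesic distance >= 3."""
    return synthetic.make_separated_models(5, 3, min_dist=3.0, seed=1)


@pytest.fixture(scope="session")
def three_class(separated_models):
    """Well-separated three-class dataset (30 per class, tangent sd 0.3)
    with its pairwise geodesic distance matrix."""
    mats, labels = synthetic.make_three_class(
        separated_models, per_class=30, sd=0.3, seed=2
    )
    dist = geometry.pairwise_distances(mats, geometry.GeometrySpec())
    return mats, labels, dist
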