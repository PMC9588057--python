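"""Geometry primitives: submersion, AIRM, fiber optimization, quotient metric."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from corrmanifold import geometry
from corrmanifold.geometry import (
    GeometrySpec,
    InvalidMatrixError,
    corr_dist,
    corr_exp,
    corr_log,
    fiber_optimize,
    pairwise_distances,
    spd_dist,
    spd_exp,
    spd_log,
    submersion,
)
from conftest import airm_dist_2x2_grid, corr2, rand_corr


class TestSubmersion:
    @pytest.mark.parametrize(
        "S, expected",
        [
            ([[4.0, 1.0], [1.0, 1.0]], [[1.0, 0.5], [0.5, 1.0]]),
            (
                [[2.0, -1.0, 0.0], [-1.0, 2.0, -1.0], [0.0, -1.0, 2.0]],
                [[1.0, -0.5, 0.0], [-0.5, 1.0, -0.5], [0.0, -0.5, 1.0]],
            ),
        ],
    )
    def test_known_values(self, S, expected):
        np.testing.assert_allclose(submersion(np.array(S)), expected, atol=1e-15)

    def test_fixes_correlation_matrices(self):
        C = rand_corr(4, 7)
        np.testing.assert_allclose(submersion(C), C, atol=1e-14)

    def test_idempotent_with_exact_unit_diagonal(self):
        rng = np.random.default_rng(5)
        G = rng.standard_normal((6, 12))
        C = submersion(G @ G.T)
        assert np.all(np.diag(C) == 1.0)
        np.testing.assert_allclose(submersion(C), C, atol=1e-15)

    def test_rejects_non_pd(self):
        with pytest.raises(InvalidMatrixError, match="eigenvalue|diagonal"):
            submersion(np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestAmbientAIRM:
    def test_commuting_scalar_case(self):
        assert spd_dist(np.eye(3), np.eye(3)) == 0.0
        np.testing.assert_allclose(
            spd_dist(2 * np.eye(3), 8 * np.eye(3)), np.sqrt(3) * np.log(4)
        )

    def test_matches_eigendecomposition_oracle(self):
        # independent oracle: sum of squared log-eigenvalues of A^{-1/2}BA^{-1/2}
        rng = np.random.default_rng(11)
        G1, G2 = rng.standard_normal((2, 4, 8))
        A, B = G1 @ G1.T, G2 @ G2.T
        wA, UA = np.linalg.eigh(A)
        Ai = UA @ np.diag(wA**-0.5) @ UA.T
        lam = np.linalg.eigvalsh(Ai @ B @ Ai)
        np.testing.assert_allclose(
            spd_dist(A, B), np.sqrt(np.sum(np.log(lam) ** 2)), rtol=1e-12
        )

    def test_exp_log_basics(self):
        np.testing.assert_allclose(
            spd_exp(np.eye(2), np.diag([1.0, 2.0])), np.diag([np.e, np.e**2])
        )
        A = rand_corr(4, 3)
        np.testing.assert_allclose(spd_log(A, A), np.zeros((4, 4)), atol=1e-12)

    def test_exp_log_round_trip_and_norm(self):
        rng = np.random.default_rng(21)
        base = rand_corr(4, 13)
        V = rng.standard_normal((4, 4))
        V = 0.5 * (V + V.T)
        X = spd_exp(base, V)
        np.testing.assert_allclose(spd_log(base, X), V, atol=1e-8)
        assert abs(geometry.airm_norm(base, spd_log(base, X)) - spd_dist(base, X)) < 1e-10

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            spd_dist(np.eye(2), np.eye(3))


class TestFiberOptimization:
    def test_identical_pair_gives_identity(self):
        C = rand_corr(4, 2)
        scal = fiber_optimize(C, C)
        np.testing.assert_allclose(scal.log_entries, 0.0, atol=1e-6)
        assert scal.objective < 1e-12

    def test_matches_grid_oracle_2x2(self):
        C1, C2 = corr2(0.5), corr2(0.0)
        d_grid, (d1, d2) = airm_dist_2x2_grid(C1, C2)
        scal = fiber_optimize(C1, C2)
        assert abs(np.sqrt(scal.objective) - d_grid) < 1e-2
        np.testing.assert_allclose(scal.entries, [d1, d2], atol=2e-3)

    def test_objective_no_worse_than_identity(self):
        C1, C2 = rand_corr(5, 31), rand_corr(5, 32)
        scal = fiber_optimize(C1, C2)
        assert np.sqrt(scal.objective) <= spd_dist(C1, C2) + 1e-10

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        C1, C2 = rand_corr(5, 41), rand_corr(5, 42)
        P = np.eye(5)[rng.permutation(5)]
        scal = fiber_optimize(C1, C2)
        scal_p = fiber_optimize(P @ C1 @ P.T, P @ C2 @ P.T)
        np.testing.assert_allclose(P @ scal.entries, scal_p.entries, atol=1e-6)

    def test_exact_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(17)
        C1, C2 = rand_corr(4, 51), rand_corr(4, 52)
        A = geometry.spd_invsqrtm(C1)[None]
        X = rng.standard_normal((1, 4)) * 0.3
        _, g = geometry._batch_objective_grad(A, C2[None], X)
        h = 1e-6
        for j in range(4):
            e = np.zeros(4)
            e[j] = h
            fp, _ = geometry._batch_objective_grad(A, C2[None], X + e, want_grad=False)
            fm, _ = geometry._batch_objective_grad(A, C2[None], X - e, want_grad=False)
            assert abs(g[0, j] - (fp[0] - fm[0]) / (2 * h)) < 1e-6


class TestQuotientMetric:
    def test_zero_on_diagonal_and_symmetry(self):
        C1, C2 = rand_corr(4, 61), rand_corr(4, 62)
        assert corr_dist(C1, C1) < 1e-7
        assert abs(corr_dist(C1, C2) - corr_dist(C2, C1)) < 1e-6

    def test_quotient_bound_over_random_fiber_points(self):
        # the quotient distance is the infimum over the fiber of C2
        rng = np.random.default_rng(9)
        C1, C2 = rand_corr(4, 71), rand_corr(4, 72)
        d = corr_dist(C1, C2)
        for _ in range(100):
            dd = np.exp(rng.standard_normal(4) * 0.5)
            assert d <= spd_dist(C1, dd[:, None] * C2 * dd[None, :]) + 1e-8

    def test_triangle_inequality(self):
        mats = np.array([rand_corr(4, 100 + i) for i in range(12)])
        D = pairwise_distances(mats, GeometrySpec())
        rng = np.random.default_rng(4)
        for _ in range(50):
            i, j, k = rng.choice(12, 3, replace=False)
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-8

    def test_permutation_invariance(self):
        rng = np.random.default_rng(14)
        C1, C2 = rand_corr(5, 81), rand_corr(5, 82)
        P = np.eye(5)[rng.permutation(5)]
        assert abs(corr_dist(P @ C1 @ P.T, P @ C2 @ P.T) - corr_dist(C1, C2)) < 1e-6

    def test_log_exp_round_trip(self):
        C1, C2 = rand_corr(4, 91), rand_corr(4, 92)
        V = corr_log(C1, C2)
        np.testing.assert_allclose(corr_exp(C1, V), C2, atol=1e-6)
        assert abs(geometry.airm_norm(C1, V) - corr_dist(C1, C2)) < 1e-6

    def test_exp_yields_valid_correlation(self):
        rng = np.random.default_rng(6)
        C = rand_corr(4, 55)
        for _ in range(5):
            V = rng.standard_normal((4, 4))
            V = 0.5 * (V + V.T)
            out = corr_exp(C, V)
            geometry.validate_correlation(out)
            assert np.all(np.diag(out) == 1.0)

    def test_exp_overflow_guard(self):
        C = rand_corr(3, 1)
        with pytest.raises(OverflowError, match="norm"):
            corr_exp(C, 1e12 * np.eye(3))


class TestPairwiseDistances:
    def test_trivial_cases(self):
        C = rand_corr(3, 5)
        assert pairwise_distances(C[None]).shape == (1, 1)
        np.testing.assert_allclose(
            pairwise_distances(np.array([C, C])), np.zeros((2, 2)), atol=1e-7
        )

    def test_euclidean_printed_pair(self):
        D = pairwise_distances(
            np.array([corr2(0.5), corr2(0.0)]), GeometrySpec("euclidean")
        )
        np.testing.assert_allclose(D[0, 1], np.sqrt(2) * 0.5)

    def test_batch_agrees_with_single_solves(self):
        mats = np.array([rand_corr(5, 200 + i) for i in range(6)])
        D = pairwise_distances(mats, GeometrySpec())
        for i in range(6):
            for j in range(i + 1, 6):
                assert abs(D[i, j] - corr_dist(mats[i], mats[j])) < 1e-9

    @pytest.mark.parametrize("name", ["correlation", "spd", "euclidean"])
    def test_metric_axioms_all_geometries(self, name):
        mats = np.array([rand_corr(4, 300 + i) for i in range(5)])
        D = pairwise_distances(mats, GeometrySpec(name))
        assert np.all(np.diag(D) == 0)
        np.testing.assert_allclose(D, D.T, atol=1e-12)
        assert D[np.triu_indices(5, 1)].min() > 0

    def test_mixed_dimensions_rejected(self):
        with pytest.raises(ValueError, match="square|stack"):
            pairwise_distances([np.eye(2), np.eye(3)])


class TestValidation:
    def test_rejects_bad_diagonal(self):
        C = rand_corr(3, 9).copy()
        C[0, 0] = 0.99
        with pytest.raises(InvalidMatrixError, match="diagonal"):
            geometry.validate_correlation(C)

    def test_rejects_near_singular(self):
        C = corr2(1 - 1e-14)
        with pytest.raises(InvalidMatrixError):
            geometry.validate_correlation(C)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000), rho=st.floats(-0.95, 0.95))
def test_quotient_distance_never_exceeds_ambient(seed, rho):
    """The fiber infimum is bounded by the ambient distance at D = I."""
    C1 = rand_corr(3, seed)
    C2 = geometry.submersion(
        np.array([[1.0, rho, 0.0], [rho, 1.0, 0.1], [0.0, 0.1, 1.0]])
    )
    assert corr_dist(C1, C2) <= spd_dist(C1, C2) + 1e-8
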