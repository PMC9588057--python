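"""Clustering algorithms and validity indices under geodesic distances."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from corrmanifold import cluster, geometry
from corrmanifold.cluster import (
    CH_SENTINEL,
    affinity_graph,
    ch_index,
    kmeans,
    kmedoids,
    silhouette,
    spectral,
)
from corrmanifold.geometry import GeometrySpec, pairwise_distances
from conftest import rand_corr


def toy_two_cluster_dist():
    """4 points, 2 tight pairs: d(1,2)=d(3,4)=1, cross distances 10."""
    D = np.full((4, 4), 10.0)
    D[0, 1] = D[1, 0] = 1.0
    D[2, 3] = D[3, 2] = 1.0
    np.fill_diagonal(D, 0.0)
    return D


class TestKMeans:
    def test_k_equals_n(self):
        mats = np.array([rand_corr(4, i) for i in range(4)])
        res = kmeans(mats, K=4, seed=0)
        assert sorted(res.labels) == [1, 2, 3, 4]
        assert res.objective_trace[-1] < 1e-10

    def test_k_equals_one_gives_frechet_mean(self):
        from corrmanifold.central import frechet_mean

        mats = np.array([rand_corr(4, 10 + i) for i in range(5)])
        res = kmeans(mats, K=1, seed=0)
        assert set(res.labels) == {1}
        mu = frechet_mean(mats, eps=1e-7).center
        np.testing.assert_allclose(res.centroids[0], mu, atol=1e-4)

    def test_recovers_separable_classes(self, three_class):
        mats, labels, _ = three_class
        res = kmeans(mats, K=3, seed=0)
        assert adjusted_rand_score(labels, res.labels) == 1.0

    def test_objective_monotone(self, three_class):
        mats, _, _ = three_class
        res = kmeans(mats[:40], K=2, seed=1)
        tr = res.objective_trace
        assert all(b <= a + 1e-8 for a, b in zip(tr, tr[1:]))

    def test_k_too_large(self):
        with pytest.raises(ValueError, match="K must be"):
            kmeans(np.array([np.eye(3)]), K=2)


class TestKMedoids:
    def test_single_cluster_brute_force_medoid(self):
        # 3 points on a line: the middle one minimizes average distance
        D = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 2.0], [3.0, 2.0, 0.0]])
        res = kmedoids(D, K=1, seed=0)
        assert res.medoid_indices.tolist() == [1]

    def test_duplicated_points_zero_objective(self):
        D = np.zeros((3, 3))
        res = kmedoids(D, K=1, seed=0)
        assert res.objective_trace[-1] == 0.0

    def test_recovers_separable_classes(self, three_class):
        _, labels, dist = three_class
        res = kmedoids(dist, K=3, seed=0)
        assert adjusted_rand_score(labels, res.labels) == 1.0

    def test_objective_monotone(self, three_class):
        _, _, dist = three_class
        res = kmedoids(dist, K=4, seed=3)
        tr = res.objective_trace
        assert all(b <= a + 1e-10 for a, b in zip(tr, tr[1:]))


class TestSpectral:
    def test_coincident_groups_perfect_split(self):
        # two groups of coincident points: block-constant affinity
        D = np.full((6, 6), 5.0)
        D[:3, :3] = 0.0
        D[3:, 3:] = 0.0
        np.fill_diagonal(D, 0.0)
        res = spectral(dist=D, K=2, knn=2, seed=0)
        assert adjusted_rand_score([0, 0, 0, 1, 1, 1], res.labels) == 1.0

    def test_affinity_of_identical_matrices_is_one(self):
        C = rand_corr(4, 3)
        D = pairwise_distances(np.array([C, C, C]), GeometrySpec())
        g = affinity_graph(D, knn=1)
        np.testing.assert_allclose(g.S, 1.0)

    def test_recovers_separable_classes(self, three_class):
        _, labels, dist = three_class
        res = spectral(dist=dist, K=3, knn=7, seed=0)
        assert adjusted_rand_score(labels, res.labels) == 1.0

    def test_requires_dist_or_data(self):
        with pytest.raises(ValueError, match="data or a distance"):
            spectral(K=2)


class TestSilhouette:
    def test_hand_computed_toy(self):
        score, s = silhouette(toy_two_cluster_dist(), [1, 1, 2, 2])
        np.testing.assert_allclose(s, 0.9)
        np.testing.assert_allclose(score, 0.9)

    def test_zero_within_distance_scores_one(self):
        D = np.full((4, 4), 7.0)
        D[0, 1] = D[1, 0] = 0.0
        D[2, 3] = D[3, 2] = 0.0
        np.fill_diagonal(D, 0.0)
        score, _ = silhouette(D, [1, 1, 2, 2])
        assert score == 1.0

    def test_invariant_to_label_renaming(self):
        D = toy_two_cluster_dist()
        s1, _ = silhouette(D, [1, 1, 2, 2])
        s2, _ = silhouette(D, [2, 2, 1, 1])
        assert s1 == s2

    def test_matches_sklearn_on_random_partition(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(0)
        mats = np.array([rand_corr(4, 100 + i) for i in range(10)])
        D = pairwise_distances(mats, GeometrySpec())
        labels = rng.integers(1, 3, size=10)
        if len(np.unique(labels)) < 2:
            labels[0] = 3 - labels[0]
        ours, _ = silhouette(D, labels)
        np.testing.assert_allclose(
            ours, silhouette_score(D, labels, metric="precomputed"), rtol=1e-10
        )

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError, match="two clusters"):
            silhouette(toy_two_cluster_dist(), [1, 1, 1, 1])


class TestCHIndex:
    def test_degenerate_duplicated_groups(self):
        C1, C2 = rand_corr(3, 5), rand_corr(3, 6)
        mats = np.array([C1, C1, C2, C2])
        with pytest.warns(RuntimeWarning, match="cohesion"):
            val = ch_index(mats, [1, 1, 2, 2])
        assert val == CH_SENTINEL

    def test_mirror_symmetric_labelings(self, three_class):
        mats, _, _ = three_class
        sub = mats[[0, 1, 30, 31]]
        a = ch_index(sub, [1, 1, 2, 2])
        b = ch_index(sub, [2, 2, 1, 1])
        np.testing.assert_allclose(a, b, rtol=1e-8)

    def test_peaks_at_true_k(self, three_class):
        mats, _, dist = three_class
        vals = {}
        for K in (2, 3, 4):
            res = kmedoids(dist, K=K, seed=0)
            vals[K] = ch_index(mats, res.labels)
        assert vals[3] > vals[2] and vals[3] > vals[4]

    def test_invalid_k(self):
        mats = np.array([rand_corr(3, i) for i in range(3)])
        with pytest.raises(ValueError, match="CH index"):
            ch_index(mats, [1, 1, 1])
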