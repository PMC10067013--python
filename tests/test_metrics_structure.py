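"""Global/local structure metrics against brute-force oracles."""

import numpy as np
import pytest

from cytobench import (
    build_neighbors,
    cluster_centroids,
    compute_pcd,
    global_emd,
    global_spearman,
    knn_score,
    npe,
)
from cytobench.metrics_structure import minmax_normalize

import oracles


class TestCentroidsAndPCD:
    def test_single_cluster_mean(self):
        cents, ids = cluster_centroids(np.array([[0.0, 0.0], [2.0, 2.0]]), [0, 0])
        np.testing.assert_array_equal(cents, [[1.0, 1.0]])
        assert ids == [0]

    def test_singleton_clusters_identity(self, rng):
        X = rng.normal(size=(6, 3))
        cents, _ = cluster_centroids(X, list(range(6)))
        np.testing.assert_allclose(cents, X)

    def test_centroids_match_loop_oracle(self, rng):
        X = rng.normal(size=(100, 5))
        labels = rng.integers(0, 3, size=100)
        cents, _ = cluster_centroids(X, labels)
        expected = np.vstack([X[labels == c].mean(axis=0) for c in [0, 1, 2]])
        np.testing.assert_allclose(cents, expected, atol=1e-12)

    def test_pcd_345_triangle(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        pcd = compute_pcd(X, centroids=np.array([[0.0, 0.0], [3.0, 4.0]]))
        np.testing.assert_allclose(pcd.dists, [[0.0, 5.0], [5.0, 0.0]], atol=1e-12)

    def test_pcd_shape_and_oracle(self, blobs_200):
        X, labels = blobs_200
        pcd = compute_pcd(X, labels=labels)
        assert pcd.dists.shape == (200, 3)
        np.testing.assert_allclose(
            pcd.dists, oracles.pcd_loop(X, list(labels)), atol=1e-9
        )


class TestGlobalSpearman:
    def test_self_correlation(self, blobs_200):
        X, labels = blobs_200
        pcd = compute_pcd(X, labels=labels)
        assert global_spearman(pcd, pcd) == pytest.approx(1.0)

    def test_rank_reversal(self, blobs_200):
        X, labels = blobs_200
        pcd = compute_pcd(X, labels=labels)
        rev = pcd.dists.max() - pcd.dists
        assert global_spearman(pcd.dists, rev) == pytest.approx(-1.0)

    def test_worked_example(self):
        # flattened (1,2,3,4) vs (1,3,2,4): sum d^2 = 2 -> rho = 0.8
        assert global_spearman(
            np.array([[1.0, 2.0], [3.0, 4.0]]), np.array([[1.0, 3.0], [2.0, 4.0]])
        ) == pytest.approx(0.8, abs=1e-12)

    def test_constant_vector_is_na(self):
        assert np.isnan(global_spearman(np.ones((2, 2)), np.arange(4.0).reshape(2, 2)))

    def test_monotone_invariance(self, rng):
        a = rng.random((10, 3))
        b = rng.random((10, 3))
        base = global_spearman(a, b)
        assert global_spearman(np.exp(a), b) == pytest.approx(base, abs=1e-12)
        assert global_spearman(a, b**3 + 5) == pytest.approx(base, abs=1e-12)

    def test_matches_loop_oracle(self, rng):
        a, b = rng.random(40), rng.random(40)
        got = global_spearman(a.reshape(8, 5), b.reshape(8, 5))
        assert got == pytest.approx(oracles.spearman_loop(a, b), abs=1e-9)


class TestGlobalEMD:
    def test_identical_zero(self, rng):
        v = rng.random((5, 4))
        assert global_emd(v, v) == 0.0

    def test_piecewise_cdf_example(self):
        # min-max leaves these untouched; EMD((0,1),(0,.5,1)) = 1/6
        assert global_emd(np.array([0.0, 1.0]), np.array([0.0, 0.5, 1.0])) == (
            pytest.approx(1 / 6, abs=1e-12)
        )

    def test_constant_vectors_zero(self):
        assert global_emd(np.full(4, 7.0), np.full(6, -2.0)) == 0.0

    def test_symmetry_and_triangle(self, rng):
        a, b, c = rng.random(30), rng.random(30), rng.random(30)
        dab, dba = global_emd(a, b), global_emd(b, a)
        assert dab == pytest.approx(dba, abs=1e-12)
        assert dab <= global_emd(a, c) + global_emd(c, b) + 1e-12

    def test_matches_loop_oracle(self, rng):
        a, b = rng.random(25), rng.random(35)
        expected = oracles.wasserstein_1d_loop(
            oracles.minmax_loop(list(a)), oracles.minmax_loop(list(b))
        )
        assert global_emd(a, b) == pytest.approx(expected, abs=1e-9)

    def test_minmax_constant_to_zeros(self):
        np.testing.assert_array_equal(minmax_normalize(np.full(3, 4.2)), np.zeros(3))


class TestNeighbors:
    def test_two_cells(self):
        nb = build_neighbors(np.array([[0.0], [1.0]]), k=1, mode="exact")
        assert nb.neighbors[0, 0] == 1 and nb.neighbors[1, 0] == 0

    def test_exact_matches_quadratic_oracle(self, rng):
        X = rng.normal(size=(200, 4))
        nb = build_neighbors(X, k=10, mode="exact")
        expected = oracles.knn_loop(X, 10)
        for i in range(200):
            assert set(nb.neighbors[i].tolist()) == expected[i]

    def test_k_saturation(self, rng):
        X = rng.normal(size=(7, 2))
        nb = build_neighbors(X, k=100, mode="exact")
        assert nb.k == 6
        for i in range(7):
            assert set(nb.neighbors[i].tolist()) == set(range(7)) - {i}

    def test_approximate_recall(self, rng):
        # Gaussian-mixture fixture; mean recall vs exact must be >= 0.95
        centers = rng.normal(scale=6, size=(5, 8))
        X = np.vstack([rng.normal(c, 1.0, size=(1000, 8)) for c in centers])
        exact = build_neighbors(X, k=30, mode="exact")
        approx = build_neighbors(X, k=30, mode="approximate", seed=0)
        recall = np.mean(
            [
                len(np.intersect1d(exact.neighbors[i], approx.neighbors[i])) / 30
                for i in range(len(X))
            ]
        )
        assert recall >= 0.95


class TestKNNScore:
    def test_identical_sets(self, rng):
        nb = build_neighbors(rng.normal(size=(50, 3)), k=5, mode="exact")
        assert knn_score(nb, nb) == 1.0

    def test_hand_enumeration_zero(self):
        orig = build_neighbors(np.array([[0.0], [1.0], [10.0], [11.0]]), k=1, mode="exact")
        emb = build_neighbors(np.array([[0.0], [10.0], [1.0], [11.0]]), k=1, mode="exact")
        assert knn_score(orig, emb) == 0.0

    def test_rigid_transform_invariance(self, rng):
        X = rng.normal(size=(80, 3))
        theta = 0.7
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        Y = 3.0 * (X @ R.T) + np.array([5.0, -2.0, 1.0])
        a = build_neighbors(X, k=7, mode="exact")
        b = build_neighbors(Y, k=7, mode="exact")
        assert knn_score(a, b) == 1.0

    def test_matches_loop_oracle(self, rng):
        X, Y = rng.normal(size=(60, 4)), rng.normal(size=(60, 2))
        a = build_neighbors(X, k=8, mode="exact")
        b = build_neighbors(Y, k=8, mode="exact")
        expected = oracles.knn_score_loop(
            oracles.knn_loop(X, 8), oracles.knn_loop(Y, 8), 8
        )
        assert knn_score(a, b) == pytest.approx(expected, abs=1e-12)


class TestNPE:
    def test_identity_is_zero(self, rng):
        # overlapping clusters so the proportion vectors are estimable
        X = np.vstack(
            [rng.normal([0, 0], 1.0, (60, 2)), rng.normal([2.5, 0], 1.0, (60, 2))]
        )
        labels = np.repeat([0, 1], 60)
        nb = build_neighbors(X, k=15, mode="exact")
        assert npe(nb, nb, labels) == pytest.approx(0.0, abs=1e-12)

    def test_all_constant_proportions_is_na(self):
        # two tight, far-apart pairs: every cell's neighborhood is purely
        # its own cluster in both spaces -> every cluster skipped
        X = np.array([[0.0], [0.01], [100.0], [100.01]])
        nb = build_neighbors(X, k=1, mode="exact")
        assert np.isnan(npe(nb, nb, [0, 0, 1, 1]))

    def test_matches_double_implementation(self, rng):
        centers = np.array([[0.0, 0.0], [6.0, 0.0]])
        X = np.vstack([rng.normal(c, 1.2, size=(60, 2)) for c in centers])
        labels = np.repeat([0, 1], 60)
        emb = X[rng.permutation(len(X))]  # label-shuffled embedding
        nb_o = build_neighbors(X, k=12, mode="exact")
        nb_e = build_neighbors(emb, k=12, mode="exact")
        got = npe(nb_o, nb_e, labels)
        expected = oracles.npe_loop(
            [set(r) for r in nb_o.neighbors],
            [set(r) for r in nb_e.neighbors],
            list(labels),
            k=12,
        )
        assert got > 0
        assert got == pytest.approx(expected, abs=1e-9)

    def test_relabeling_invariance(self, rng):
        X = np.vstack(
            [rng.normal([0, 0], 1.0, (60, 2)), rng.normal([2.0, 0], 1.0, (60, 2)),
             rng.normal([0, 2.0], 1.0, (80, 2))]
        )
        labels = np.repeat([0, 1, 2], [60, 60, 80])
        emb = X + rng.normal(0, 0.8, size=X.shape)
        nb_o = build_neighbors(X, k=10, mode="exact")
        nb_e = build_neighbors(emb, k=10, mode="exact")
        base = npe(nb_o, nb_e, labels)
        renamed = np.array(["xyz"[int(c)] for c in labels])
        assert npe(nb_o, nb_e, renamed) == pytest.approx(base, abs=1e-12)
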