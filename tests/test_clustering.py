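"""Dimensionality reduction, clusterer contracts, silhouette and grid
selection."""

import numpy as np
import pytest
from sklearn.metrics import silhouette_score as sklearn_silhouette

import semharm as sh
from semharm.clustering import (DEFAULT_MIN_CLUSTER_SIZE_GRID, NOISE,
                                SILHOUETTE_SENTINEL)


def brute_force_silhouette(X, labels):
    """O(n^2) oracle straight from the definition."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    keep = labels != NOISE
    X, labels = X[keep], labels[keep]
    vals = []
    for i in range(len(X)):
        own = [j for j in range(len(X)) if labels[j] == labels[i] and j != i]
        if not own:
            vals.append(0.0)
            continue
        a = np.mean([np.linalg.norm(X[i] - X[j]) for j in own])
        b = min(
            np.mean([np.linalg.norm(X[i] - X[j])
                     for j in range(len(X)) if labels[j] == other])
            for other in set(labels) if other != labels[i]
        )
        vals.append((b - a) / max(a, b))
    return float(np.mean(vals))


def _blobs(rng, centers, n_per, scale=0.5):
    X, labels = [], []
    for c, centre in enumerate(centers):
        X.append(rng.normal(loc=centre, scale=scale,
                            size=(n_per, len(centre))))
        labels += [c] * n_per
    return np.vstack(X), np.array(labels)


class TestReduceDimensions:
    def test_identity_returns_input(self):
        X = np.random.default_rng(0).normal(size=(10, 6))
        out = sh.reduce_dimensions(X, sh.ReductionConfig(method="identity"))
        np.testing.assert_array_equal(out, X)

    def test_pca_deterministic_and_shapes(self):
        X = np.random.default_rng(1).normal(size=(30, 10))
        cfg = sh.ReductionConfig(method="pca", target_dim=3, seed=4)
        out1 = sh.reduce_dimensions(X, cfg)
        out2 = sh.reduce_dimensions(X, cfg)
        assert out1.shape == (30, 3)
        np.testing.assert_array_equal(out1, out2)

    def test_pca_recovers_collinear_points_exactly(self):
        # 3 collinear points in 3-D carry all variance on one component
        direction = np.array([1.0, 2.0, -1.0])
        X = np.outer([0.0, 1.0, 3.0], direction)
        from sklearn.decomposition import PCA
        pca = PCA(n_components=1, svd_solver="full")
        Z = pca.fit_transform(X)
        recon = pca.inverse_transform(Z)
        np.testing.assert_allclose(recon, X, atol=1e-9)
        assert pca.explained_variance_ratio_[0] == pytest.approx(1.0)

    def test_target_dim_too_large_fails(self):
        X = np.zeros((20, 5))
        with pytest.raises(ValueError, match="target_dim"):
            sh.reduce_dimensions(X, sh.ReductionConfig(method="pca",
                                                       target_dim=5))

    def test_umap_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        X, _ = _blobs(rng, [[0] * 8, [6] * 8], 20)
        cfg = sh.ReductionConfig(method="umap", target_dim=2, seed=7)
        out1 = sh.reduce_dimensions(X, cfg)
        out2 = sh.reduce_dimensions(X, cfg)
        assert out1.shape == (40, 2)
        np.testing.assert_array_equal(out1, out2)


class TestClustererConfig:
    def test_parameters_present_iff_required(self):
        with pytest.raises(ValueError, match="requires"):
            sh.ClustererConfig(algorithm="kmeans")
        with pytest.raises(ValueError, match="not used"):
            sh.ClustererConfig(algorithm="kmeans", k=3, min_samples=5)
        sh.ClustererConfig(algorithm="hdbscan", min_cluster_size=5,
                           min_samples=5)


class TestClusterAssignments:
    def test_kmeans_saturation_singletons(self):
        X = np.arange(10, dtype=float).reshape(5, 2) * 7
        ids = list("abcde")
        a = sh.cluster_assignments(
            X, ids, sh.ClustererConfig(algorithm="kmeans", k=5, seed=0))
        assert a.n_clusters == 5 and a.n_noise == 0

    def test_hac_full_merge_above_max_distance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(12, 4))
        a = sh.cluster_assignments(
            X, [str(i) for i in range(12)],
            sh.ClustererConfig(algorithm="hac", linkage_threshold=100.0,
                               hac_metric="euclidean"))
        assert a.n_clusters == 1

    def test_hdbscan_recovers_two_separated_blobs(self):
        rng = np.random.default_rng(4)
        X, _ = _blobs(rng, [[0, 0], [10, 10]], 50, scale=1.0)
        a = sh.cluster_assignments(
            X, [str(i) for i in range(100)],
            sh.ClustererConfig(algorithm="hdbscan", min_cluster_size=10,
                               min_samples=5))
        assert a.n_clusters == 2 and a.n_noise == 0

    def test_kmeans_k_exceeding_n_fails(self):
        with pytest.raises(ValueError, match="exceeds"):
            sh.cluster_assignments(
                np.zeros((3, 2)), list("abc"),
                sh.ClustererConfig(algorithm="kmeans", k=4))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        X, _ = _blobs(rng, [[0, 0], [5, 5], [0, 8]], 20)
        ids = [str(i) for i in range(60)]
        cfg = sh.ClustererConfig(algorithm="kmeans", k=3, seed=12)
        assert sh.cluster_assignments(X, ids, cfg) == \
            sh.cluster_assignments(X, ids, cfg)


class TestSilhouette:
    def test_duplicate_point_two_cluster_value_one(self):
        X = np.array([[0, 0], [0, 0], [1, 0], [1, 0]], dtype=float)
        assert sh.silhouette_score(X, np.array([0, 0, 1, 1])) == 1.0

    def test_hand_computed_one_dimensional_case(self):
        X = np.array([[0.0], [1.0], [5.0], [6.0]])
        labels = np.array([0, 0, 1, 1])
        expected = np.mean([4.5 / 5.5, 3.5 / 4.5, 3.5 / 4.5, 4.5 / 5.5])
        assert sh.silhouette_score(X, labels) == pytest.approx(
            expected, abs=1e-12)
        assert expected == pytest.approx(0.797979797979798, abs=1e-12)

    def test_single_cluster_sentinel(self):
        with pytest.warns(RuntimeWarning):
            v = sh.silhouette_score(np.zeros((4, 2)), np.zeros(4, dtype=int))
        assert v == SILHOUETTE_SENTINEL

    def test_noise_excluded_before_computation(self):
        X = np.array([[0, 0], [0, 0], [1, 0], [1, 0], [50, 50]], dtype=float)
        labels = np.array([0, 0, 1, 1, NOISE])
        assert sh.silhouette_score(X, labels) == 1.0

    def test_matches_brute_force_and_sklearn(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            n = int(rng.integers(8, 60))
            k = int(rng.integers(2, 5))
            X = rng.normal(size=(n, 3))
            labels = rng.integers(0, k, size=n)
            if len(np.unique(labels)) < 2:
                continue
            ours = sh.silhouette_score(X, labels)
            assert ours == pytest.approx(brute_force_silhouette(X, labels),
                                         abs=1e-10)
            assert ours == pytest.approx(
                sklearn_silhouette(X, labels), abs=1e-8)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(7)
        X, labels = _blobs(rng, [[0, 0], [4, 4]], 15)
        perm = rng.permutation(len(X))
        assert sh.silhouette_score(X[perm], labels[perm]) == pytest.approx(
            sh.silhouette_score(X, labels), abs=1e-12)


class TestSelectBestConfiguration:
    def test_singleton_grid_selected(self):
        rng = np.random.default_rng(8)
        X, _ = _blobs(rng, [[0, 0], [6, 6]], 20)
        ids = [str(i) for i in range(40)]
        res = sh.select_best_configuration(
            X, [sh.ReductionConfig(method="identity")],
            [sh.ClustererConfig(algorithm="kmeans", k=2, seed=0)],
            identifiers=ids)
        assert res.selected.n_clusters == 2
        assert len(res.rows) == 1

    def test_silhouette_maximum_at_true_k(self):
        rng = np.random.default_rng(9)
        X, _ = _blobs(rng, [[0, 0], [8, 0], [0, 8], [8, 8], [4, 16]], 20,
                      scale=0.3)
        ids = [str(i) for i in range(100)]
        res = sh.select_best_configuration(
            X, [sh.ReductionConfig(method="identity")],
            [sh.ClustererConfig(algorithm="kmeans", k=k, seed=0)
             for k in (2, 5, 20)],
            identifiers=ids)
        assert res.selected.clusterer.k == 5
        assert res.selected.silhouette == max(
            r.silhouette for r in res.rows if r.valid)

    def test_all_single_cluster_fails(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(20, 3))
        ids = [str(i) for i in range(20)]
        with pytest.raises(RuntimeError, match="no valid clustering"):
            sh.select_best_configuration(
                X, [sh.ReductionConfig(method="identity")],
                [sh.ClustererConfig(algorithm="hac", linkage_threshold=1e9,
                                    hac_metric="euclidean")],
                identifiers=ids)

    def test_hdbscan_cluster_count_monotone_in_min_cluster_size(
            self, planted_five_domains):
        _, _, E = planted_five_domains
        X = E.vectors
        counts = []
        for mcs in DEFAULT_MIN_CLUSTER_SIZE_GRID:
            a = sh.cluster_assignments(
                X, E.identifiers,
                sh.ClustererConfig(algorithm="hdbscan", min_cluster_size=mcs,
                                   min_samples=5))
            counts.append(a.n_clusters)
        assert all(c1 >= c2 for c1, c2 in zip(counts, counts[1:]))
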