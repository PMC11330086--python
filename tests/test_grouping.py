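import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from chemgroup.fixtures import make_feature_blobs
from chemgroup.grouping import (
    ClusterSpec,
    ProjectionSpec,
    SearchSpace,
    SilhouetteUndefinedError,
    default_search_space,
    project_2d,
    run_clustering,
    silhouette,
    tune_grouping,
)
from tests.conftest import brute_force_silhouette


class TestSilhouette:
    def test_coincident_far_clusters_score_one(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0], [9.0, 9.0], [9.0, 9.0]])
        assert silhouette(pts, np.array([0, 0, 1, 1])) == 1.0

    def test_hand_evaluated_two_pair_case(self):
        # clusters {(0,0),(0,1)} and {(10,0),(10,1)}: a=1, b=(10+sqrt(101))/2
        pts = np.array([[0, 0], [0, 1], [10, 0], [10, 1]], dtype=float)
        a, b = 1.0, (10 + np.sqrt(101)) / 2
        expected = (b - a) / b
        assert silhouette(pts, np.array([0, 0, 1, 1])) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.900, abs=5e-4)

    def test_single_cluster_is_signaled_not_nan(self):
        pts = np.random.default_rng(0).random((10, 2))
        with pytest.raises(SilhouetteUndefinedError):
            silhouette(pts, np.zeros(10, dtype=int))

    def test_noise_points_excluded(self):
        pts = np.array([[0, 0], [0, 1], [10, 0], [10, 1], [500, 500]], dtype=float)
        labels = np.array([0, 0, 1, 1, -1])
        no_noise = silhouette(pts[:4], labels[:4])
        assert silhouette(pts, labels) == no_noise

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        pts = rng.random((40, 3))
        labels = rng.integers(0, 3, size=40)
        perm = {0: 2, 1: 0, 2: 1}
        relabeled = np.array([perm[c] for c in labels])
        assert silhouette(pts, labels) == pytest.approx(
            silhouette(pts, relabeled), abs=1e-15
        )

    def test_agrees_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(10, 60))
            k = int(rng.integers(2, 5))
            pts = rng.normal(size=(n, 3))
            labels = rng.integers(0, k, size=n)
            if len(np.unique(labels)) < 2:
                continue
            assert silhouette(pts, labels) == pytest.approx(
                brute_force_silhouette(pts, labels), abs=1e-9
            )


class TestProject2D:
    def test_pca_collinear_input_flat_second_axis(self):
        t = np.linspace(0, 1, 30)
        pts = np.column_stack([t, 2 * t])
        emb = project_2d(pts, ProjectionSpec("pca", seed=0))
        assert emb.shape == (30, 2)
        assert emb[:, 1].var() < 1e-20

    def test_tsne_perplexity_precondition(self):
        pts = np.random.default_rng(0).random((20, 3))
        with pytest.raises(ValueError, match="perplexity"):
            project_2d(pts, ProjectionSpec("tsne", {"perplexity": 10.0}, seed=0))

    def test_umap_parameter_validation(self):
        pts = np.random.default_rng(0).random((10, 3))
        with pytest.raises(ValueError, match="n_neighbors"):
            project_2d(pts, ProjectionSpec("umap", {"n_neighbors": 50}, seed=0))

    def test_umap_deterministic_and_separation_preserving(self):
        X, y = make_feature_blobs(90, 3, 10, 20, seed=0)
        spec = ProjectionSpec("umap", {"n_neighbors": 10, "min_dist": 0.1}, seed=5)
        e1 = project_2d(X, spec)
        e2 = project_2d(X, spec)
        assert np.array_equal(e1, e2)
        # blob pairs stay separated: min inter-blob > max intra-blob distance
        from scipy.spatial.distance import cdist

        intra = max(
            cdist(e1[y == c], e1[y == c]).max() for c in range(3)
        )
        inter = min(
            cdist(e1[y == a], e1[y == b]).min()
            for a in range(3) for b in range(a + 1, 3)
        )
        assert inter > intra


class TestRunClustering:
    def test_kmeans_recovers_far_blobs(self):
        X, y = make_feature_blobs(120, 2, 6, 20, seed=1)
        labels = run_clustering(X, ClusterSpec("kmeans", {"n_clusters": 2}, seed=0))
        assert adjusted_rand_score(y, labels) == 1.0

    def test_kmedoids_recovers_far_blobs_with_exactly_k(self):
        X, y = make_feature_blobs(90, 3, 6, 20, seed=2)
        labels = run_clustering(X, ClusterSpec("kmedoids", {"n_clusters": 3}, seed=0))
        assert len(set(labels.tolist())) == 3
        assert adjusted_rand_score(y, labels) == 1.0

    @pytest.mark.parametrize("linkage", ["single", "complete", "average"])
    @pytest.mark.parametrize("metric", ["euclidean", "manhattan"])
    def test_hierarchical_linkages_and_metrics(self, linkage, metric):
        X, y = make_feature_blobs(60, 2, 4, 20, seed=3)
        labels = run_clustering(
            X,
            ClusterSpec("hierarchical",
                        {"n_clusters": 2, "linkage": linkage, "metric": metric}),
        )
        assert adjusted_rand_score(y, labels) == 1.0

    def test_hierarchical_n_clusters_equals_n(self):
        X, _ = make_feature_blobs(12, 2, 3, 5, seed=0)
        labels = run_clustering(X, ClusterSpec("hierarchical", {"n_clusters": 12}))
        assert len(set(labels.tolist())) == 12

    def test_dbscan_tiny_epsilon_all_noise(self):
        X, _ = make_feature_blobs(30, 2, 3, 10, seed=0)
        labels = run_clustering(X, ClusterSpec("dbscan", {"eps": 1e-9, "min_samples": 2}))
        assert set(labels.tolist()) == {-1}

    def test_hdbscan_finds_blobs(self):
        X, y = make_feature_blobs(90, 3, 5, 20, seed=4)
        labels = run_clustering(X, ClusterSpec("hdbscan", {"min_cluster_size": 5}))
        mask = labels != -1
        assert adjusted_rand_score(y[mask], labels[mask]) > 0.99

    def test_k_exceeding_n_errors(self):
        X, _ = make_feature_blobs(10, 2, 3, 5, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            run_clustering(X, ClusterSpec("kmeans", {"n_clusters": 11}))


class TestTuneGrouping:
    def test_single_trial_equals_that_trial(self):
        X, _ = make_feature_blobs(60, 3, 6, 20, seed=0)
        space = SearchSpace({"cluster__n_clusters": ("int", 3, 3)}, n_trials=1, seed=0)
        res = tune_grouping(X, "kmeans", "pca", space, projected=True)
        assert len(res.tuning_trace) == 1
        assert res.tuning_trace[0][1] == res.silhouette

    def test_best_trace_entry_matches_returned_silhouette(self):
        X, _ = make_feature_blobs(80, 3, 6, 20, seed=1)
        space = SearchSpace({"cluster__n_clusters": ("int", 2, 8)}, n_trials=10, seed=0)
        res = tune_grouping(X, "kmeans", "pca", space, projected=True)
        assert max(s for _, s in res.tuning_trace) == res.silhouette

    def test_reproducible_end_to_end_with_fixed_seed(self):
        X, _ = make_feature_blobs(70, 3, 5, 15, seed=2)
        space = SearchSpace({"cluster__n_clusters": ("int", 2, 6)}, n_trials=8, seed=3)
        r1 = tune_grouping(X, "kmeans", "pca", space, projected=True)
        r2 = tune_grouping(X, "kmeans", "pca", space, projected=True)
        assert np.array_equal(r1.labels, r2.labels)
        assert r1.silhouette == r2.silhouette

    def test_two_stage_mode_keeps_full_space_labels(self):
        X, y = make_feature_blobs(70, 3, 6, 20, seed=4)
        space = SearchSpace({"cluster__n_clusters": ("int", 2, 6)}, n_trials=8, seed=0)
        res = tune_grouping(X, "kmeans", "pca", space, projected=False)
        assert res.full_space_labels is not None
        assert adjusted_rand_score(y, res.full_space_labels) == 1.0
        assert res.embedding.shape == (70, 2)

    def test_all_degenerate_trials_error(self):
        X, _ = make_feature_blobs(30, 2, 3, 5, seed=0)
        space = SearchSpace({"cluster__eps": ("float", 1e-9, 1e-8),
                             "cluster__min_samples": ("int", 2, 3)},
                            n_trials=3, seed=0)
        with pytest.raises(ValueError, match="degenerate"):
            tune_grouping(X, "dbscan", "pca", space, projected=True)

    def test_default_search_space_mirrors_case_study_ranges(self):
        space = default_search_space("kmedoids", "umap")
        assert space.params["cluster__n_clusters"] == ("int", 2, 25)
        assert space.params["proj__min_dist"] == ("float", 0.01, 0.25)
        assert space.params["proj__n_neighbors"] == ("int", 2, 50)
        assert space.n_trials == 50
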