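"""Clustering, label alignment, classifier battery and the 2-D ordination."""

import numpy as np
import pandas as pd
import pytest

import woodstrid as ws
from woodstrid.features import FEATURE_COLUMNS, FeatureTable, normalize_features
from woodstrid.identification import NOISE_LABEL


def blobs_table(d, n=100, seed=0):
    """Two species clouds at Euclidean separation d (in sd units)."""
    tables = ws.generate_feature_benchmark(
        separation_schedule={5.0: d, 60.0: 0.0}, n_per_species=n, seed=seed
    )
    return normalize_features(tables[5.0])


def wide_blobs_table(n=100, seed=0):
    """Blobs whose means differ by 10 sd along every feature."""
    return blobs_table(d=10.0 * np.sqrt(5.0), n=n, seed=seed)


class TestAccuracy:
    def test_perfect(self):
        assert ws.accuracy(ws.ConfusionCounts(50, 50, 0, 0)) == 100.0

    def test_all_wrong(self):
        assert ws.accuracy(ws.ConfusionCounts(0, 0, 10, 10)) == 0.0

    def test_direct_evaluation(self):
        assert ws.accuracy(ws.ConfusionCounts(40, 45, 10, 5)) == 85.0

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            ws.accuracy(ws.ConfusionCounts(0, 0, 0, 0))


class TestAlignment:
    def test_inverted_labels_align_to_perfect(self):
        truth = np.array([0, 0, 1, 1] * 10)
        conf = ws.align_cluster_labels(1 - truth, truth)
        assert ws.accuracy(conf) == 100.0

    def test_single_cluster_balanced_truth(self):
        truth = np.array([0, 1] * 20)
        conf = ws.align_cluster_labels(np.zeros(40, dtype=int), truth)
        assert ws.accuracy(conf) == 50.0

    def test_noise_points_count_as_errors(self):
        truth = np.array([0, 0, 1, 1])
        pred = np.array([0, NOISE_LABEL, 1, 1])
        conf = ws.align_cluster_labels(pred, truth)
        assert ws.accuracy(conf) == 75.0

    def test_random_labels_near_chance(self):
        rng = np.random.default_rng(8)
        truth = np.repeat([0, 1], 100)
        accs = [
            ws.accuracy(
                ws.align_cluster_labels(rng.integers(0, 2, 200), truth)
            )
            for _ in range(50)
        ]
        # best-of-two-permutations null: folded binomial around 50%
        assert 50.0 <= np.mean(accs) <= 56.0

    def test_three_clusters_best_map_flagged_path(self):
        truth = np.repeat([0, 1], 30)
        pred = np.concatenate([np.zeros(30), np.ones(15), np.full(15, 2)])
        conf = ws.align_cluster_labels(pred.astype(int), truth)
        assert ws.accuracy(conf) == 100.0  # majority map is exact here


class TestClustering:
    @pytest.mark.parametrize("method", ["kmeans", "fcm", "gmm"])
    def test_well_separated_blobs_recovered(self, method):
        table = blobs_table(d=10.0)
        labels = ws.cluster_features(
            table, ws.ClusterConfig(method=method, seed=1)
        )
        truth = table.data["species"].to_numpy()
        assert ws.accuracy(ws.align_cluster_labels(labels, truth)) == 100.0

    @pytest.mark.parametrize("method", ["kmeans", "fcm", "gmm"])
    def test_identical_distributions_at_chance(self, method):
        tables = ws.generate_feature_benchmark(
            separation_schedule={5.0: 0.0, 60.0: 0.0},
            n_per_species=250,
            seed=5,
        )
        table = normalize_features(tables[5.0])
        labels = ws.cluster_features(
            table, ws.ClusterConfig(method=method, seed=2)
        )
        truth = table.data["species"].to_numpy()
        acc = ws.accuracy(ws.align_cluster_labels(labels, truth))
        assert 45.0 <= acc <= 55.0  # within the binomial chance band

    def test_dbscan_min_points_above_n_gives_all_noise(self):
        table = blobs_table(d=10.0, n=20)
        cfg = ws.ClusterConfig(method="dbscan", min_points=50)
        # scaled min_points still exceeds cluster density at tiny n?
        labels = ws.cluster_features(table, cfg)
        assert set(labels) <= {NOISE_LABEL, 0, 1}

    def test_deterministic_given_seed(self):
        table = blobs_table(d=3.0)
        cfg = ws.ClusterConfig(method="fcm", seed=11)
        a = ws.cluster_features(table, cfg)
        b = ws.cluster_features(table, cfg)
        assert np.array_equal(a, b)

    def test_unnormalized_table_rejected(self):
        df = pd.DataFrame(
            {c: np.random.default_rng(0).normal(0, 5, 10) for c in FEATURE_COLUMNS}
        )
        with pytest.raises(ValueError):
            ws.cluster_features(FeatureTable(df), ws.ClusterConfig())


class TestClassifiers:
    @pytest.mark.parametrize("method", ws.CLASSIFIER_METHODS)
    def test_separable_blobs_high_accuracy(self, method):
        table = wide_blobs_table(seed=2)
        acc, folds = ws.classify_cv(
            table, ws.ClassifierConfig(method=method, seed=0)
        )
        assert acc >= 99.0
        assert len(folds) == 5

    @pytest.mark.parametrize("method", ["lda", "svm_rbf", "knn_euclidean"])
    def test_shuffled_labels_at_chance(self, method):
        table = blobs_table(d=10.0, n=150, seed=3)
        rng = np.random.default_rng(7)
        df = table.data.copy()
        df["species"] = rng.permutation(df["species"].to_numpy())
        shuffled = FeatureTable(df, norm_bounds=table.norm_bounds)
        acc, _ = ws.classify_cv(
            shuffled, ws.ClassifierConfig(method=method, seed=0)
        )
        assert 42.0 <= acc <= 58.0

    def test_five_features_beat_duration_alone(self):
        """At an overlapping distance the full battery input wins."""
        tables = ws.generate_feature_benchmark(
            separation_schedule={30.0: 2.0, 60.0: 0.0},
            n_per_species=250,
            seed=4,
        )
        table = normalize_features(tables[30.0])
        cfg = ws.ClassifierConfig(method="lda", seed=0)
        full, _ = ws.classify_cv(table, cfg)
        dur_only, _ = ws.classify_cv(
            table, cfg, feature_columns=("duration_s",)
        )
        assert full > dur_only

    def test_training_accuracy_is_perfect_on_separable_data(self):
        from woodstrid.identification import make_classifier

        table = blobs_table(d=10.0, seed=6)
        X = table.feature_matrix()
        y = table.data["species"].to_numpy()
        for method in ("tree", "lda", "svm_rbf", "knn_euclidean"):
            clf = make_classifier(ws.ClassifierConfig(method=method, seed=0))
            clf.fit(X, y)
            assert np.mean(clf.predict(X) == y) == 1.0

    def test_deterministic_given_seed(self):
        table = blobs_table(d=2.0, seed=9)
        cfg = ws.ClassifierConfig(method="bag_tree", seed=5)
        assert ws.classify_cv(table, cfg) == ws.classify_cv(table, cfg)


class TestEvaluateByDistance:
    def test_sup_and_unsup_agree_on_separable_data(self, small_benchmark):
        sub = {5.0: small_benchmark[5.0]}
        acc = ws.evaluate_by_distance(
            sub,
            cluster_methods=("kmeans", "gmm"),
            classifier_methods=("lda", "svm_rbf"),
            seed=0,
        )
        vals = acc[5.0].to_numpy(dtype=float)
        assert vals.max() - vals.min() <= 3.0
        assert np.all(vals >= 97.0)

    def test_accuracy_declines_with_distance(self, small_benchmark):
        acc = ws.evaluate_by_distance(
            small_benchmark,
            cluster_methods=("kmeans",),
            classifier_methods=("lda", "knn_euclidean"),
            seed=0,
        )
        for alg in acc.index:
            vals = acc.loc[alg].to_numpy(dtype=float)
            assert vals[0] >= vals[-1]
            assert 45.0 <= vals[-1] <= 55.0

    def test_single_species_distance_left_unscored(self):
        table = blobs_table(d=5.0, n=30)
        df = table.data[table.data["species"] == "H_ater"].reset_index(drop=True)
        solo = FeatureTable(df, norm_bounds=table.norm_bounds)
        acc = ws.evaluate_by_distance(
            {5.0: table, 60.0: solo},
            cluster_methods=("kmeans",),
            classifier_methods=(),
            seed=0,
        )
        assert np.isnan(acc.loc["kmeans", 60.0])
        assert acc.loc["kmeans", 5.0] > 90.0


class TestEmbed2d:
    def test_separable_blobs_keep_silhouette(self):
        from sklearn.metrics import silhouette_score

        table = blobs_table(d=10.0, n=60, seed=1)
        coords = ws.embed_2d(table, seed=0)
        labels = table.data["species"].to_numpy()
        assert silhouette_score(coords, labels) > 0.5

    def test_duplicate_rows_embed_close(self):
        df = pd.DataFrame(
            {c: np.tile([0.1, 0.9], 10) for c in FEATURE_COLUMNS}
        )
        coords = ws.embed_2d(FeatureTable(df), seed=0)
        same = coords[::2]
        spread = np.linalg.norm(same - same.mean(axis=0), axis=1).max()
        other = np.linalg.norm(coords[0] - coords[1])
        assert spread < other

    def test_same_seed_identical(self):
        table = blobs_table(d=4.0, n=40, seed=2)
        a = ws.embed_2d(table, seed=3)
        b = ws.embed_2d(table, seed=3)
        assert np.array_equal(a, b)
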