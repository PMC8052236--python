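import math

import numpy as np
import pytest

from ecogloc.classify import (
    DEPTH,
    ECOG,
    NON_ELECTRODE,
    EvaluationReport,
    GSVMConfig,
    LabeledDataset,
    assemble_dataset,
    compute_report,
    crossvalidate_kfold,
    evaluate_transfer,
    feature_subset_ablation,
    load_model,
    predict,
    save_model,
    train_gsvm,
)
from ecogloc.shape_features import FEATURE_COLUMNS


def blobs_dataset(n_per_class=50, separation=10.0, seed=0, name="blobs"):
    """Two well-separated 6-feature Gaussian blobs."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, 1.0, size=(n_per_class, 6))
    b = rng.normal(separation, 1.0, size=(n_per_class, 6))
    X = np.vstack([a, b])
    y = np.array([ECOG] * n_per_class + [NON_ELECTRODE] * n_per_class, dtype=object)
    groups = np.array(["p0"] * len(X), dtype=object)
    return LabeledDataset(feature_matrix=X, labels=y, groups=groups, name=name)


def xor_dataset(n_per_cluster=25, seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for cx, cy, label in [
        (0, 0, ECOG),
        (8, 8, ECOG),
        (0, 8, NON_ELECTRODE),
        (8, 0, NON_ELECTRODE),
    ]:
        pts = rng.normal([cx, cy], 0.8, size=(n_per_cluster, 2))
        X.append(pts)
        y += [label] * n_per_cluster
    X = np.vstack(X)
    return LabeledDataset(
        feature_matrix=X,
        labels=np.array(y, dtype=object),
        groups=np.array(["p0"] * len(X), dtype=object),
        name="xor",
        feature_names=("f0", "f1"),
    )


class TestGSVMConfig:
    def test_defaults(self):
        cfg = GSVMConfig()
        assert cfg.box_constraint == 1.0
        assert cfg.kernel_scale_mode == "feature_scaled"
        assert cfg.standardize is True
        assert cfg.class_weighting == "none"

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"box_constraint": 0},
            {"kernel_scale_mode": "bogus"},
            {"kernel_scale_mode": "value"},  # missing kernel_scale
            {"class_weighting": "heavy"},
            {"multiclass": "one_vs_rest"},
        ],
    )
    def test_rejects_bad_config(self, kwargs):
        with pytest.raises(ValueError):
            GSVMConfig(**kwargs)


class TestTrainPredict:
    def test_separable_blobs_training_accuracy_100(self):
        data = blobs_dataset()
        model = train_gsvm(data, GSVMConfig())
        pred, _ = predict(model, data.feature_matrix)
        assert np.all(pred == data.labels)

    def test_xor_rbf_beats_linear(self):
        from sklearn.svm import SVC

        data = xor_dataset()
        model = train_gsvm(data, GSVMConfig())
        pred, _ = predict(model, data.feature_matrix)
        rbf_acc = np.mean(pred == data.labels)
        linear = SVC(kernel="linear", C=1.0).fit(
            data.feature_matrix, data.labels.astype(str)
        )
        lin_acc = np.mean(linear.predict(data.feature_matrix) == data.labels.astype(str))
        assert rbf_acc > 0.95
        assert lin_acc <= 0.75

    def test_single_class_rejected(self):
        data = blobs_dataset()
        data.labels[:] = ECOG
        with pytest.raises(ValueError):
            train_gsvm(data)

    def test_nonfinite_features_rejected(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            LabeledDataset(
                feature_matrix=X,
                labels=np.array([ECOG, ECOG, NON_ELECTRODE, NON_ELECTRODE]),
                groups=np.array(["p"] * 4),
            )

    def test_three_class_one_vs_one(self):
        rng = np.random.default_rng(3)
        X = np.vstack(
            [rng.normal(c, 0.5, size=(20, 6)) for c in (0.0, 10.0, 20.0)]
        )
        y = np.array([ECOG] * 20 + [DEPTH] * 20 + [NON_ELECTRODE] * 20, dtype=object)
        data = LabeledDataset(X, y, np.array(["p"] * 60), name="3c")
        model = train_gsvm(data)
        assert sorted(model.classes) == sorted([ECOG, DEPTH, NON_ELECTRODE])
        pred, _ = predict(model, X)
        assert np.all(pred == y)

    def test_predict_empty(self):
        model = train_gsvm(blobs_dataset())
        pred, scores = predict(model, np.empty((0, 6)))
        assert len(pred) == 0 and len(scores) == 0

    def test_predict_dimension_mismatch(self):
        model = train_gsvm(blobs_dataset())
        with pytest.raises(ValueError):
            predict(model, np.ones((3, 5)))

    def test_deterministic(self):
        data = blobs_dataset(separation=2.0)
        m1 = train_gsvm(data, GSVMConfig(seed=7))
        m2 = train_gsvm(data, GSVMConfig(seed=7))
        X = np.random.default_rng(0).normal(1.0, 2.0, size=(40, 6))
        p1, s1 = predict(m1, X)
        p2, s2 = predict(m2, X)
        assert np.all(p1 == p2)
        np.testing.assert_array_equal(s1, s2)

    def test_model_roundtrip(self, tmp_path):
        data = blobs_dataset()
        model = train_gsvm(data)
        save_model(model, tmp_path / "model.joblib")
        loaded = load_model(tmp_path / "model.joblib")
        assert loaded.classes == model.classes
        X = data.feature_matrix
        np.testing.assert_array_equal(predict(loaded, X)[0], predict(model, X)[0])


class TestComputeReport:
    def test_hand_counted_binary(self):
        rep = compute_report(
            ["E", "E", "E", "N"], ["E", "E", "N", "N"], class_universe=["E", "N"]
        )
        assert rep.accuracy == pytest.approx(75.0)
        assert rep.per_class_sensitivity["E"] == pytest.approx(100 * 2 / 3)
        assert rep.per_class_specificity["E"] == pytest.approx(100.0)
        assert rep.n_instances == 4

    def test_perfect_three_class_identity_percent(self):
        y = [ECOG, DEPTH, NON_ELECTRODE] * 4
        rep = compute_report(y, y)
        np.testing.assert_allclose(rep.confusion_percent, 100.0 * np.eye(3))
        assert rep.accuracy == 100.0

    def test_all_wrong_binary(self):
        rep = compute_report(["A", "B"], ["B", "A"])
        assert rep.accuracy == 0.0
        assert rep.per_class_sensitivity["A"] == 0.0
        assert rep.per_class_sensitivity["B"] == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_report(["A"], ["A", "B"])

    def test_rows_sum_to_support_and_percent_100(self):
        rng = np.random.default_rng(1)
        y_true = rng.choice(["A", "B", "C"], size=200)
        y_pred = rng.choice(["A", "B", "C"], size=200)
        rep = compute_report(y_true, y_pred)
        for i, c in enumerate(rep.classes):
            assert rep.confusion_counts[i].sum() == np.sum(y_true == c)
            assert rep.confusion_percent[i].sum() == pytest.approx(100.0, abs=1e-6)
        assert rep.accuracy == pytest.approx(
            100.0 * np.mean(y_true == y_pred), abs=1e-9
        )

    def test_report_serialization(self, tmp_path):
        rep = compute_report(["A", "B"], ["A", "B"])
        rep.to_json(tmp_path / "rep.json")
        rep.confusion_to_csv(tmp_path / "conf.csv")
        import json

        payload = json.loads((tmp_path / "rep.json").read_text())
        assert payload["accuracy"] == 100.0


class TestCrossValidation:
    def test_separable_blobs_accuracy_100(self):
        rep = crossvalidate_kfold(blobs_dataset(), k=10, seed=0)
        assert rep.fold_mean_accuracy == 100.0
        assert rep.accuracy == 100.0
        assert len(rep.per_fold_accuracy) == 10

    def test_same_seed_identical_report(self):
        data = blobs_dataset(separation=1.5)
        r1 = crossvalidate_kfold(data, k=5, seed=42)
        r2 = crossvalidate_kfold(data, k=5, seed=42)
        np.testing.assert_array_equal(r1.confusion_counts, r2.confusion_counts)
        assert r1.per_fold_accuracy == r2.per_fold_accuracy

    def test_pooled_accuracy_close_to_fold_mean(self):
        rep = crossvalidate_kfold(blobs_dataset(separation=1.0), k=10, seed=0)
        assert abs(rep.accuracy - rep.fold_mean_accuracy) < 0.5

    @pytest.mark.parametrize("k", [0, 1])
    def test_k_below_two_rejected(self, k):
        with pytest.raises(ValueError):
            crossvalidate_kfold(blobs_dataset(), k=k)

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            crossvalidate_kfold(blobs_dataset(n_per_class=3), k=10)

    def test_shuffle_invariance_of_fold_mean(self):
        data = blobs_dataset(separation=1.2, n_per_class=40)
        rep1 = crossvalidate_kfold(data, k=5, seed=9)
        perm = np.random.default_rng(5).permutation(len(data))
        shuffled = LabeledDataset(
            data.feature_matrix[perm], data.labels[perm], data.groups[perm]
        )
        rep2 = crossvalidate_kfold(shuffled, k=5, seed=9)
        # folds are derived from canonically sorted instances, so the
        # report ignores input row order entirely
        np.testing.assert_array_equal(rep1.confusion_counts, rep2.confusion_counts)
        assert rep1.per_fold_accuracy == rep2.per_fold_accuracy


class TestTransfer:
    def test_self_test_is_100(self):
        data = blobs_dataset()
        model = train_gsvm(data)
        reports, mean, sd = evaluate_transfer(model, [data])
        assert mean == 100.0 and sd == 0.0

    def test_identical_sets_sd_zero(self):
        data = blobs_dataset(separation=1.0)
        model = train_gsvm(data)
        _, mean, sd = evaluate_transfer(model, [data, data])
        assert sd == 0.0

    def test_unknown_class_rejected(self):
        model = train_gsvm(blobs_dataset())
        bad = blobs_dataset()
        bad.labels[0] = DEPTH
        with pytest.raises(ValueError):
            evaluate_transfer(model, [bad])

    def test_labels_not_used_for_prediction(self):
        data = blobs_dataset(separation=1.0)
        model = train_gsvm(data)
        scrambled = LabeledDataset(
            data.feature_matrix,
            data.labels[::-1].copy(),
            data.groups,
            name="scrambled",
        )
        p1, _ = predict(model, data.feature_matrix)
        reports, _, _ = evaluate_transfer(model, [scrambled])
        # confusion columns (predictions) identical whatever the labels say
        assert reports[0].confusion_counts.sum(axis=0).tolist() == [
            int(np.sum(p1 == c)) for c in reports[0].classes
        ]


class TestAssembleDataset:
    def _table(self, n, patient, label=ECOG):
        from ecogloc.shape_features import ClusterFeatures, FeatureTable

        rows = [
            ClusterFeatures(
                cluster_id=i + 1,
                volume=10 + i,
                primary_axis=3.0,
                secondary_axis=2.0,
                tertiary_axis=1.0,
                circularity=1.5,
                cylinder_similarity=1.2,
                centroid_voxel=(0, 0, 0),
                centroid_mm=(0, 0, 0),
            )
            for i in range(n)
        ]
        return FeatureTable(rows=rows, patient_id=patient, true_class=[label] * n)

    def test_concatenation(self):
        data = assemble_dataset(
            [self._table(10, "p1"), self._table(15, "p2", NON_ELECTRODE)], name="C1"
        )
        assert len(data) == 25
        assert data.name == "C1"
        assert set(data.groups) == {"p1", "p2"}

    def test_single_table(self):
        data = assemble_dataset([self._table(7, "p1")])
        assert len(data) == 7

    def test_unlabeled_table_rejected(self):
        t = self._table(4, "p1")
        t.true_class = None
        with pytest.raises(ValueError):
            assemble_dataset([t])


class TestAblation:
    def test_contains_volume_only_and_full_set(self):
        table = feature_subset_ablation(blobs_dataset(), seed=0, k=5)
        assert len(table) >= 2
        assert "volume" in set(table.features)
        assert "+".join(FEATURE_COLUMNS) in set(table.features)
        assert (table.n_features >= 1).all()

    def test_all_features_separable_is_100(self):
        table = feature_subset_ablation(blobs_dataset(), seed=0, k=5)
        full = table[table.features == "+".join(FEATURE_COLUMNS)]
        assert full.cv_accuracy.iloc[0] == 100.0

    def test_subset_without_volume_rejected(self):
        with pytest.raises(ValueError):
            feature_subset_ablation(
                blobs_dataset(), seed=0, k=5, subsets=[("circularity",)]
            )
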