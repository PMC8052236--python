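"""Gaussian-kernel SVM classification of metal clusters.

Separates ECoG (and depth) electrodes from other metal objects using the
six geometric features, with stratified tenfold cross-validation,
cross-dataset transfer evaluation and confusion-matrix metrics
(rows = true classes, columns = predicted classes).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ecogloc.shape_features import FEATURE_COLUMNS, FeatureTable

__all__ = [
    "ECOG",
    "DEPTH",
    "NON_ELECTRODE",
    "LabeledDataset",
    "GSVMConfig",
    "TrainedClassifier",
    "EvaluationReport",
    "assemble_dataset",
    "train_gsvm",
    "predict",
    "crossvalidate_kfold",
    "evaluate_transfer",
    "compute_report",
    "feature_subset_ablation",
    "save_model",
    "load_model",
]

ECOG = "ECOG"
DEPTH = "DEPTH"
NON_ELECTRODE = "NON_ELECTRODE"
CLASS_UNIVERSE = (ECOG, DEPTH, NON_ELECTRODE)

MODEL_FORMAT_VERSION = 1


@dataclass
class LabeledDataset:
    """Feature matrix with per-instance class labels and patient groups."""

    feature_matrix: np.ndarray
    labels: np.ndarray
    groups: np.ndarray
    name: str = ""
    feature_names: tuple[str, ...] = FEATURE_COLUMNS

    def __post_init__(self) -> None:
        self.feature_matrix = np.asarray(self.feature_matrix, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.groups = np.asarray(self.groups, dtype=object)
        if self.feature_matrix.ndim != 2:
            raise ValueError("feature_matrix must be 2D")
        n = len(self.feature_matrix)
        if len(self.labels) != n or len(self.groups) != n:
            raise ValueError("labels/groups length must match feature_matrix rows")
        if n and not np.all(np.isfinite(self.feature_matrix)):
            raise ValueError("feature_matrix contains non-finite values")

    def __len__(self) -> int:
        return len(self.feature_matrix)

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    def select_features(self, names: tuple[str, ...]) -> "LabeledDataset":
        idx = [self.feature_names.index(n) for n in names]
        return LabeledDataset(
            feature_matrix=self.feature_matrix[:, idx],
            labels=self.labels,
            groups=self.groups,
            name=self.name,
            feature_names=tuple(names),
        )


@dataclass
class GSVMConfig:
    """Hyperparameters of the Gaussian (RBF) SVM.

    kernel_scale_mode: "unit" (gamma = 1), "feature_scaled"
    (gamma = 1 / (n_features * total feature variance), the common
    heuristic) or "value" (use ``kernel_scale``).
    """

    box_constraint: float = 1.0
    kernel_scale_mode: str = "feature_scaled"
    kernel_scale: float | None = None
    standardize: bool = True
    class_weighting: str = "none"
    multiclass: str = "one_vs_one"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.box_constraint > 0:
            raise ValueError("box_constraint must be > 0")
        if self.kernel_scale_mode not in ("unit", "feature_scaled", "value"):
            raise ValueError(f"unknown kernel_scale_mode {self.kernel_scale_mode!r}")
        if self.kernel_scale_mode == "value" and not (
            self.kernel_scale and self.kernel_scale > 0
        ):
            raise ValueError("kernel_scale must be > 0 in 'value' mode")
        if self.class_weighting not in ("none", "balanced"):
            raise ValueError(f"unknown class_weighting {self.class_weighting!r}")
        if self.multiclass != "one_vs_one":
            raise ValueError("only one_vs_one multiclass is supported")

    def _gamma(self):
        if self.kernel_scale_mode == "unit":
            return 1.0
        if self.kernel_scale_mode == "value":
            return float(self.kernel_scale)
        return "scale"

    def build_estimator(self) -> Pipeline:
        svc = SVC(
            C=self.box_constraint,
            kernel="rbf",
            gamma=self._gamma(),
            class_weight=None if self.class_weighting == "none" else "balanced",
            decision_function_shape="ovo",
            random_state=self.seed,
        )
        steps = [("standardize", StandardScaler())] if self.standardize else []
        return Pipeline(steps + [("gsvm", svc)])


@dataclass
class TrainedClassifier:
    """A fitted G-SVM pipeline plus its training metadata."""

    estimator: Pipeline
    classes: list[str]
    feature_names: tuple[str, ...]
    config: GSVMConfig
    dataset_name: str = ""

    @property
    def n_features(self) -> int:
        return len(self.feature_names)


@dataclass
class EvaluationReport:
    """Confusion matrix and derived metrics for one classification run.

    ``accuracy`` is the pooled percent correct
    (100 * trace(confusion_counts) / n_instances). For cross-validation
    runs ``per_fold_accuracy`` is set and ``fold_mean_accuracy`` gives
    the mean of the per-fold accuracies — the conventional k-fold
    figure; on stratified folds the two agree closely.
    """

    classes: list[str]
    confusion_counts: np.ndarray
    confusion_percent: np.ndarray
    accuracy: float
    per_class_sensitivity: dict[str, float]
    per_class_specificity: dict[str, float]
    n_instances: int
    per_fold_accuracy: list[float] | None = None

    @property
    def fold_mean_accuracy(self) -> float:
        if self.per_fold_accuracy is None:
            return self.accuracy
        return float(np.mean(self.per_fold_accuracy))

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "confusion_counts": self.confusion_counts.tolist(),
            "confusion_percent": self.confusion_percent.tolist(),
            "accuracy": self.accuracy,
            "fold_mean_accuracy": self.fold_mean_accuracy,
            "per_class_sensitivity": self.per_class_sensitivity,
            "per_class_specificity": self.per_class_specificity,
            "n_instances": self.n_instances,
            "per_fold_accuracy": self.per_fold_accuracy,
        }

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def confusion_to_csv(self, path: str | os.PathLike) -> None:
        pd.DataFrame(
            self.confusion_counts, index=self.classes, columns=self.classes
        ).to_csv(path, index_label="true\\predicted")


def assemble_dataset(tables: list[FeatureTable], name: str = "") -> LabeledDataset:
    """Concatenate labeled feature tables into one training dataset."""
    if not tables:
        raise ValueError("need at least one table")
    mats, labels, groups = [], [], []
    for t in tables:
        if t.true_class is None:
            raise ValueError(
                f"table for patient {t.patient_id!r} has no true_class labels"
            )
        mats.append(t.feature_matrix())
        labels.extend(t.true_class)
        groups.extend([t.patient_id] * len(t))
    return LabeledDataset(
        feature_matrix=np.vstack(mats),
        labels=np.array(labels, dtype=object),
        groups=np.array(groups, dtype=object),
        name=name,
    )


def train_gsvm(data: LabeledDataset, config: GSVMConfig | None = None) -> TrainedClassifier:
    """Fit the Gaussian SVM on a labeled dataset (2 or 3 classes)."""
    config = config or GSVMConfig()
    classes, counts = np.unique(data.labels.astype(str), return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes to train, got {list(classes)}")
    if counts.min() < 2:
        raise ValueError("every class needs >= 2 training instances")
    est = config.build_estimator()
    est.fit(data.feature_matrix, data.labels.astype(str))
    return TrainedClassifier(
        estimator=est,
        classes=[str(c) for c in est[-1].classes_],
        feature_names=data.feature_names,
        config=config,
        dataset_name=data.name,
    )


def predict(
    model: TrainedClassifier, features: FeatureTable | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predict a class (plus a decision score) for every feature row.

    The score is the maximum one-vs-one decision value — larger means a
    more confident assignment. Returns ``(classes, scores)``.
    """
    X = features.feature_matrix() if isinstance(features, FeatureTable) else np.asarray(
        features, dtype=float
    )
    if X.size == 0:
        return np.array([], dtype=object), np.array([])
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} feature columns, got shape {X.shape}"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    pred = model.estimator.predict(X).astype(object)
    dec = np.atleast_2d(model.estimator.decision_function(X))
    if dec.shape[0] != len(X):
        dec = dec.T
    scores = np.abs(dec).max(axis=1)
    return pred, scores


def compute_report(
    true_labels,
    predicted_labels,
    class_universe: list[str] | None = None,
    per_fold_accuracy: list[float] | None = None,
) -> EvaluationReport:
    """Confusion matrix, accuracy and one-vs-rest sensitivity/specificity.

    Sensitivity(c) = 100 * TP_c / (TP_c + FN_c) and specificity(c) =
    100 * TN_c / (TN_c + FP_c); confusion rows are true classes.
    """
    y_true = np.asarray(true_labels, dtype=object)
    y_pred = np.asarray(predicted_labels, dtype=object)
    if len(y_true) != len(y_pred):
        raise ValueError("true and predicted label lists differ in length")
    classes = (
        list(class_universe)
        if class_universe is not None
        else sorted(set(y_true) | set(y_pred))
    )
    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    n = int(counts.sum())
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(
            row_sums[:, None] > 0, 100.0 * counts / row_sums[:, None], 0.0
        )
    accuracy = 100.0 * np.trace(counts) / n if n else 0.0
    sens, spec = {}, {}
    for c, i in index.items():
        tp = counts[i, i]
        fn = row_sums[i] - tp
        fp = counts[:, i].sum() - tp
        tn = n - tp - fn - fp
        sens[c] = 100.0 * tp / (tp + fn) if tp + fn else float("nan")
        spec[c] = 100.0 * tn / (tn + fp) if tn + fp else float("nan")
    return EvaluationReport(
        classes=classes,
        confusion_counts=counts,
        confusion_percent=percent,
        accuracy=float(accuracy),
        per_class_sensitivity=sens,
        per_class_specificity=spec,
        n_instances=n,
        per_fold_accuracy=per_fold_accuracy,
    )


def crossvalidate_kfold(
    data: LabeledDataset,
    k: int = 10,
    config: GSVMConfig | None = None,
    seed: int = 0,
) -> EvaluationReport:
    """Seeded stratified k-fold cross-validation of the G-SVM.

    Each fold is tested on a model trained on the remaining k-1 folds;
    the report pools all held-out predictions and records the k per-fold
    accuracies (their mean is the conventional cross-validation figure).
    """
    config = config or GSVMConfig(seed=seed)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > len(data):
        raise ValueError(f"k={k} exceeds n_instances={len(data)}")
    y = data.labels.astype(str)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"every class needs >= k={k} instances for stratified folds"
        )
    # canonical instance order: folds depend on the data, not on the
    # order rows happened to arrive in
    canon = np.lexsort(tuple(data.feature_matrix.T) + (y,))
    X = data.feature_matrix[canon]
    y = y[canon]
    groups = data.groups[canon]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    y_true_all, y_pred_all, fold_acc = [], [], []
    for train_idx, test_idx in skf.split(X, y):
        fold_data = LabeledDataset(
            feature_matrix=X[train_idx],
            labels=y[train_idx],
            groups=groups[train_idx],
            name=data.name,
            feature_names=data.feature_names,
        )
        model = train_gsvm(fold_data, config)
        pred, _ = predict(model, X[test_idx])
        y_true_all.extend(y[test_idx])
        y_pred_all.extend(pred)
        fold_acc.append(100.0 * float(np.mean(pred.astype(str) == y[test_idx])))
    return compute_report(
        y_true_all,
        y_pred_all,
        class_universe=sorted(set(y)),
        per_fold_accuracy=fold_acc,
    )


def evaluate_transfer(
    model: TrainedClassifier, test_sets: list[LabeledDataset]
) -> tuple[list[EvaluationReport], float, float]:
    """Evaluate a trained model on held-out datasets.

    Returns per-set reports plus the mean and standard deviation of the
    per-set accuracies. Test labels are used only for scoring, never for
    prediction.
    """
    reports = []
    for ds in test_sets:
        unknown = set(map(str, ds.labels)) - set(model.classes)
        if unknown:
            raise ValueError(
                f"test set {ds.name!r} contains classes unknown to the model: "
                f"{sorted(unknown)}"
            )
        pred, _ = predict(model, ds.feature_matrix)
        reports.append(
            compute_report(ds.labels.astype(str), pred, class_universe=model.classes)
        )
    accs = np.array([r.accuracy for r in reports])
    mean = float(accs.mean()) if len(accs) else float("nan")
    sd = float(accs.std(ddof=1)) if len(accs) > 1 else 0.0
    return reports, mean, sd


def feature_subset_ablation(
    data: LabeledDataset,
    config: GSVMConfig | None = None,
    seed: int = 0,
    k: int = 10,
    subsets: list[tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Cross-validated accuracy for feature subsets that include volume.

    By default evaluates volume alone, volume paired with each other
    single feature, and the full six-feature set, all on identical
    seeded folds. Returns a DataFrame with columns ``features``,
    ``n_features``, ``cv_accuracy`` (mean of fold accuracies, %).
    """
    if subsets is None:
        others = [c for c in data.feature_names if c != "volume"]
        subsets = [("volume",)]
        subsets += [("volume", o) for o in others]
        subsets.append(tuple(data.feature_names))
    rows = []
    for sub in subsets:
        if "volume" not in sub:
            raise ValueError(f"every subset must contain 'volume', got {sub}")
        rep = crossvalidate_kfold(data.select_features(tuple(sub)), k=k, config=config, seed=seed)
        rows.append(
            {
                "features": "+".join(sub),
                "n_features": len(sub),
                "cv_accuracy": rep.fold_mean_accuracy,
            }
        )
    return pd.DataFrame(rows)


def save_model(model: TrainedClassifier, path: str | os.PathLike) -> None:
    """Persist a trained classifier to a single versioned file."""
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "estimator": model.estimator,
            "classes": model.classes,
            "feature_names": model.feature_names,
            "config": model.config,
            "dataset_name": model.dataset_name,
        },
        path,
    )


def load_model(path: str | os.PathLike) -> TrainedClassifier:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    return TrainedClassifier(
        estimator=payload["estimator"],
        classes=payload["classes"],
        feature_names=tuple(payload["feature_names"]),
        config=payload["config"],
        dataset_name=payload["dataset_name"],
    )
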