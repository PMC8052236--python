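"""Reproducible phantom-corpus experiments used for validation.

These are the end-to-end benchmarks run by the acceptance script and the
acceptance test suite: held-out recognition with a deliberately small
training corpus, large-corpus tenfold cross-validation with a realistic
(~1:5) electrode:distractor imbalance, and the feature-subset ablation.
"""

from __future__ import annotations

import numpy as np

from ecogloc.classify import (
    ECOG,
    GSVMConfig,
    LabeledDataset,
    assemble_dataset,
    crossvalidate_kfold,
    feature_subset_ablation,
    predict,
    train_gsvm,
)
from ecogloc.phantom import PhantomSpec, match_detections
from ecogloc.pipeline import phantom_feature_table

__all__ = [
    "small_corpus_specs",
    "large_corpus_specs",
    "held_out_sensitivity",
    "build_labeled_corpus",
    "corpus_cv_report",
    "ablation_min_accuracy",
]

#: Default phantom head radius used by the experiment corpora (mm).
_HEAD_RADIUS = 55.0


def small_corpus_specs(base_seed: int = 0, n_volumes: int = 6) -> list[PhantomSpec]:
    """Volumes for the limited-training experiment.

    Each has two strips (8 and 12 electrodes), one 6x8 grid, 10 wires,
    15 stitches and 2 screws: 68 electrodes among ~27 distractors.
    """
    return [
        PhantomSpec(
            seed=base_seed + i + 1,
            strips=(8, 12),
            grids=((6, 8),),
            n_wires=10,
            n_stitches=15,
            n_screws=2,
            head_radius=_HEAD_RADIUS,
        )
        for i in range(n_volumes)
    ]


def large_corpus_specs(base_seed: int = 0, n_volumes: int = 13) -> list[PhantomSpec]:
    """Volumes totaling ~1000 electrodes and ~5000 distractor clusters.

    Each contributes 78 electrodes (strips of 12/8/6/4 plus a 6x8 grid)
    and ~420 non-electrode objects, giving roughly the 1:5 class ratio
    of a combined multi-patient dataset.
    """
    return [
        PhantomSpec(
            seed=base_seed + 100 + i,
            strips=(12, 8, 6, 4),
            grids=((6, 8),),
            n_wires=25,
            n_stitches=380,
            n_screws=15,
            head_radius=_HEAD_RADIUS,
        )
        for i in range(n_volumes)
    ]


def held_out_sensitivity(
    specs: list[PhantomSpec],
    n_train: int,
    seed: int = 0,
    tolerance_mm: float = 2.0,
) -> tuple[float, int]:
    """Train on the first *n_train* phantoms, localize electrodes in the rest.

    Runs the full pipeline on every volume, trains the G-SVM on the
    training volumes' truth-labeled clusters, predicts the held-out
    volumes' clusters, and scores ECoG detections against ground truth
    by centroid matching. Returns ``(sensitivity_percent, n_truth)``.
    """
    if not 0 < n_train < len(specs):
        raise ValueError("n_train must leave at least one held-out volume")
    tables, truths = [], []
    for spec in specs:
        table, truth = phantom_feature_table(spec, tolerance_mm=tolerance_mm)
        tables.append(table)
        truths.append(truth)
    train_data = assemble_dataset(tables[:n_train], name="train")
    model = train_gsvm(train_data, GSVMConfig(seed=seed))
    tp = total = 0
    for table, truth in zip(tables[n_train:], truths[n_train:]):
        classes, _ = predict(model, table)
        centroids = np.array([r.centroid_mm for r in table.rows], dtype=float).reshape(
            -1, 3
        )
        result = match_detections(classes, centroids, truth, tolerance_mm)
        n_truth = len(truth.of_class(ECOG))
        tp += sum(
            1
            for o in truth.of_class(ECOG)
            if result.truth_outcomes[o.object_id] == "true_positive"
        )
        total += n_truth
    return 100.0 * tp / total, total


def build_labeled_corpus(
    specs: list[PhantomSpec], name: str = "corpus"
) -> LabeledDataset:
    """Run the pipeline on every phantom and pool the labeled clusters."""
    tables = [phantom_feature_table(spec)[0] for spec in specs]
    return assemble_dataset(tables, name=name)


def corpus_cv_report(data: LabeledDataset, seed: int = 0, k: int = 10):
    """Seeded stratified tenfold cross-validation with default G-SVM."""
    return crossvalidate_kfold(data, k=k, config=GSVMConfig(seed=seed), seed=seed)


def ablation_min_accuracy(
    data: LabeledDataset, seed: int = 0, k: int = 10
) -> tuple[float, "object"]:
    """Minimum CV accuracy across volume-containing subsets of size >= 2.

    Returns ``(min_accuracy_percent, ablation_table)``.
    """
    table = feature_subset_ablation(data, config=GSVMConfig(seed=seed), seed=seed, k=k)
    multi = table[table.n_features >= 2]
    return float(multi.cv_accuracy.min()), table
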