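"""End-to-end helpers chaining the pipeline stages.

load/resample -> threshold -> 6-connected labeling -> shape features,
plus assignment of ground-truth classes to phantom-derived clusters.
"""

from __future__ import annotations

import numpy as np

from ecogloc.ct_io import CTVolume, resample_isotropic
from ecogloc.phantom import ECOG, DEPTH, NON_ELECTRODE, GroundTruth, match_detections
from ecogloc.segmentation import ClusterLabeling, label_clusters, threshold_metal
from ecogloc.shape_features import FeatureTable, compute_feature_table

__all__ = ["extract_features", "label_table_from_truth", "phantom_feature_table"]


def extract_features(
    vol: CTVolume,
    target_spacing: float = 0.5,
    hu_threshold: float = 2500.0,
    axis_mode: str = "moment",
    patient_id: str = "",
) -> tuple[ClusterLabeling, FeatureTable]:
    """Run resample -> threshold -> label -> features on one CT volume."""
    iso = resample_isotropic(vol, target_spacing)
    labeling = label_clusters(threshold_metal(iso, hu_threshold))
    table = compute_feature_table(labeling, axis_mode=axis_mode, patient_id=patient_id)
    return labeling, table


def label_table_from_truth(
    table: FeatureTable, truth: GroundTruth, tolerance_mm: float = 2.0
) -> FeatureTable:
    """Assign each cluster its ground-truth class by centroid proximity.

    A cluster whose centroid matches an electrode-class truth object
    within the tolerance (one-to-one, closest first) inherits that
    class; all other clusters are labeled non-electrode.
    """
    centroids = np.array([r.centroid_mm for r in table.rows], dtype=float).reshape(
        -1, 3
    )
    labels = [NON_ELECTRODE] * len(table.rows)
    for cls in (ECOG, DEPTH):
        claimed = match_detections(
            np.array([cls] * len(table.rows), dtype=object),
            centroids,
            truth,
            tolerance_mm,
        )
        for _, det_idx in claimed.matches:
            labels[det_idx] = cls
    return FeatureTable(
        rows=table.rows, patient_id=table.patient_id, true_class=labels
    )


def phantom_feature_table(
    spec,
    target_spacing: float = 0.5,
    hu_threshold: float = 2500.0,
    axis_mode: str = "moment",
    tolerance_mm: float = 2.0,
):
    """Generate a phantom and return its truth-labeled feature table.

    Returns ``(table, truth)`` where the table's ``patient_id`` encodes
    the phantom seed.
    """
    from ecogloc.phantom import generate_phantom

    vol, truth = generate_phantom(spec)
    _, table = extract_features(
        vol,
        target_spacing=target_spacing,
        hu_threshold=hu_threshold,
        axis_mode=axis_mode,
        patient_id=f"phantom{spec.seed}",
    )
    return label_table_from_truth(table, truth, tolerance_mm), truth
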