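"""Six geometric shape descriptors for labeled voxel clusters.

Per cluster: voxel-count volume, the three principal axis lengths of the
moment-equivalent ellipsoid, circularity (primary/secondary axis ratio)
and cylinder similarity (volume ratio against the cylinder built from the
axes), plus the centroid in voxel and world coordinates.

Axis lengths follow the moment-equivalent-ellipsoid convention: for a
covariance eigenvalue lambda of the voxel positions (with a 1/12
voxel-spread correction per axis), the length is ``2 * sqrt(5 * lambda)``
— the axis of the solid ellipsoid having the same second central moments
as the cluster. A single voxel therefore has axes 2*sqrt(5/12) ~ 1.291.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ecogloc.segmentation import ClusterLabeling

__all__ = [
    "ClusterFeatures",
    "FeatureTable",
    "principal_axis_lengths",
    "circularity",
    "cylinder_similarity",
    "compute_feature_table",
    "FEATURE_COLUMNS",
]

#: Classifier feature columns, in canonical order.
FEATURE_COLUMNS = (
    "volume",
    "primary_axis",
    "secondary_axis",
    "tertiary_axis",
    "circularity",
    "cylinder_similarity",
)

#: Variance of a unit-width voxel about its own center (continuous moments).
VOXEL_SPREAD = 1.0 / 12.0

CSV_COLUMNS = (
    "patient_id",
    "cluster_id",
    *FEATURE_COLUMNS,
    "centroid_x_mm",
    "centroid_y_mm",
    "centroid_z_mm",
    "true_class",
)


@dataclass
class ClusterFeatures:
    """The six geometric descriptors plus centroid for one cluster."""

    cluster_id: int
    volume: int
    primary_axis: float
    secondary_axis: float
    tertiary_axis: float
    circularity: float
    cylinder_similarity: float
    centroid_voxel: tuple[float, float, float]
    centroid_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.cluster_id < 1:
            raise ValueError("cluster_id must be positive")
        if self.volume < 1:
            raise ValueError("volume must be >= 1")
        if not self.primary_axis >= self.secondary_axis >= self.tertiary_axis > 0:
            raise ValueError("axes must be sorted descending and positive")


@dataclass
class FeatureTable:
    """Per-cluster feature rows for one volume (or patient)."""

    rows: list[ClusterFeatures]
    patient_id: str = ""
    true_class: list[str] | None = None

    def __post_init__(self) -> None:
        ids = [r.cluster_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("cluster_id values must be unique within a table")
        if self.true_class is not None and len(self.true_class) != len(self.rows):
            raise ValueError("true_class must have one label per row")

    def __len__(self) -> int:
        return len(self.rows)

    def feature_matrix(self) -> np.ndarray:
        """(n, 6) array in canonical ``FEATURE_COLUMNS`` order."""
        return np.array(
            [[getattr(r, c) for c in FEATURE_COLUMNS] for r in self.rows],
            dtype=float,
        ).reshape(len(self.rows), len(FEATURE_COLUMNS))

    def to_dataframe(self) -> pd.DataFrame:
        rec = {
            "patient_id": [self.patient_id] * len(self.rows),
            "cluster_id": [r.cluster_id for r in self.rows],
        }
        for c in FEATURE_COLUMNS:
            rec[c] = [getattr(r, c) for r in self.rows]
        cents = np.array([r.centroid_mm for r in self.rows], dtype=float).reshape(
            len(self.rows), 3
        )
        rec["centroid_x_mm"] = cents[:, 0]
        rec["centroid_y_mm"] = cents[:, 1]
        rec["centroid_z_mm"] = cents[:, 2]
        rec["true_class"] = (
            list(self.true_class) if self.true_class is not None else [""] * len(self.rows)
        )
        return pd.DataFrame(rec, columns=CSV_COLUMNS)

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "FeatureTable":
        rows = [
            ClusterFeatures(
                cluster_id=int(r.cluster_id),
                volume=int(r.volume),
                primary_axis=float(r.primary_axis),
                secondary_axis=float(r.secondary_axis),
                tertiary_axis=float(r.tertiary_axis),
                circularity=float(r.circularity),
                cylinder_similarity=float(r.cylinder_similarity),
                centroid_voxel=(math.nan, math.nan, math.nan),
                centroid_mm=(
                    float(r.centroid_x_mm),
                    float(r.centroid_y_mm),
                    float(r.centroid_z_mm),
                ),
            )
            for r in df.itertuples()
        ]
        labels = None
        if "true_class" in df.columns:
            vals = df["true_class"].fillna("").astype(str).tolist()
            if any(vals):
                labels = vals
        pid = str(df["patient_id"].iloc[0]) if len(df) else ""
        return cls(rows=rows, patient_id=pid, true_class=labels)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "FeatureTable":
        return cls.from_dataframe(pd.read_csv(path))


def principal_axis_lengths(
    cluster_voxels: np.ndarray, axis_mode: str = "moment"
) -> tuple[float, float, float]:
    """Principal axis lengths of a voxel cluster, sorted descending.

    Parameters
    ----------
    cluster_voxels
        (n, 3) integer voxel indices of a nonempty cluster.
    axis_mode
        ``"moment"`` (default): axes of the ellipsoid whose second
        central moments match the cluster's, i.e. ``2*sqrt(5*lambda)``
        per covariance eigenvalue, after adding the 1/12 voxel-spread
        correction to each coordinate variance. ``"extent"``: the
        cluster's extent (max - min projection + 1 voxel) along the same
        principal directions.

    Returns
    -------
    (primary, secondary, tertiary) lengths in voxel units.
    """
    pts = np.atleast_2d(np.asarray(cluster_voxels, dtype=float))
    if pts.size == 0:
        raise ValueError("cluster is empty")
    if pts.shape[1] != 3:
        raise ValueError("cluster_voxels must be (n, 3)")
    cov = np.cov(pts, rowvar=False, ddof=0).reshape(3, 3) if len(pts) > 1 else np.zeros((3, 3))
    cov = cov + VOXEL_SPREAD * np.eye(3)
    eigval, eigvec = np.linalg.eigh(cov)  # ascending
    if axis_mode == "moment":
        lengths = 2.0 * np.sqrt(5.0 * np.clip(eigval, 0.0, None))
    elif axis_mode == "extent":
        proj = (pts - pts.mean(axis=0)) @ eigvec
        lengths = proj.max(axis=0) - proj.min(axis=0) + 1.0
    else:
        raise ValueError(f"unknown axis_mode {axis_mode!r}")
    p, s, t = np.sort(lengths)[::-1]
    return float(p), float(s), float(t)


def circularity(primary: float, secondary: float) -> float:
    """Roundness of a cluster: primary / secondary axis length (>= 1)."""
    if not secondary > 0:
        raise ValueError(f"secondary axis must be > 0, got {secondary}")
    if primary < secondary:
        raise ValueError("primary axis must be >= secondary axis")
    return primary / secondary


def cylinder_similarity(
    primary: float, secondary: float, tertiary: float, volume: float
) -> float:
    """Ratio of the axis-built cylinder's volume to the cluster volume.

    The reference cylinder has diameter ``(primary + secondary) / 2``
    and height ``tertiary``:

        ((primary + secondary) / 4)^2 * pi * tertiary / volume

    A coin-shaped cluster measured with extent-mode axes scores exactly
    1; elongated or curved clusters deviate substantially from 1.
    """
    if not (primary > 0 and secondary > 0 and tertiary > 0):
        raise ValueError("axis lengths must be > 0")
    if not volume >= 1:
        raise ValueError(f"volume must be >= 1, got {volume}")
    return ((primary + secondary) / 4.0) ** 2 * math.pi * tertiary / volume


def compute_feature_table(
    labeling: ClusterLabeling,
    axis_mode: str = "moment",
    patient_id: str = "",
) -> FeatureTable:
    """Compute one feature row per labeled cluster.

    Rows are ordered by cluster id; volume is the exact voxel count and
    the centroid is the mean voxel index, mapped to mm via the affine.
    """
    rows: list[ClusterFeatures] = []
    if labeling.n_clusters > 0:
        coords = np.argwhere(labeling.labels > 0)
        labs = labeling.labels[tuple(coords.T)]
        order = np.argsort(labs, kind="stable")
        coords, labs = coords[order], labs[order]
        counts = np.bincount(labs, minlength=labeling.n_clusters + 1)[1:]
        splits = np.cumsum(counts)[:-1]
        A, b = labeling.affine[:3, :3], labeling.affine[:3, 3]
        for cid, pts in enumerate(np.split(coords, splits), start=1):
            p, s, t = principal_axis_lengths(pts, axis_mode=axis_mode)
            vol = len(pts)
            cv = pts.mean(axis=0)
            cmm = A @ cv + b
            rows.append(
                ClusterFeatures(
                    cluster_id=cid,
                    volume=vol,
                    primary_axis=p,
                    secondary_axis=s,
                    tertiary_axis=t,
                    circularity=circularity(p, s),
                    cylinder_similarity=cylinder_similarity(p, s, t, vol),
                    centroid_voxel=tuple(cv),
                    centroid_mm=tuple(cmm),
                )
            )
    return FeatureTable(rows=rows, patient_id=patient_id)
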