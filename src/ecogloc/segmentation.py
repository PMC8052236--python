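"""Metal thresholding and 6-connected cluster labeling."""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from ecogloc.ct_io import CTVolume

__all__ = [
    "BinaryVolume",
    "ClusterLabeling",
    "threshold_metal",
    "label_clusters",
    "DEFAULT_HU_THRESHOLD",
]

#: Radiodensity above which a voxel is considered metal (above compact bone).
DEFAULT_HU_THRESHOLD = 2500.0

#: Face-adjacency structuring element (6-connectivity).
SIX_CONNECTIVITY = ndi.generate_binary_structure(3, 1)


@dataclass
class BinaryVolume:
    """Boolean metal mask sharing the grid geometry of its source volume."""

    mask: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")


@dataclass
class ClusterLabeling:
    """Integer-labeled grid of 6-connected metal clusters.

    ``labels`` holds 0 for background and 1..``n_clusters`` for clusters;
    every label in that range occurs at least once.
    """

    labels: np.ndarray
    n_clusters: int
    spacing: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be 3D")
        if self.n_clusters < 0:
            raise ValueError("n_clusters must be >= 0")

    def cluster_indices(self, cluster_id: int) -> np.ndarray:
        """Return the (n, 3) voxel indices of one cluster."""
        if not 1 <= cluster_id <= self.n_clusters:
            raise ValueError(f"cluster_id {cluster_id} out of range 1..{self.n_clusters}")
        return np.argwhere(self.labels == cluster_id)


def threshold_metal(
    vol: CTVolume, hu_threshold: float = DEFAULT_HU_THRESHOLD
) -> BinaryVolume:
    """Binarize a CT volume at a metal radiodensity threshold.

    The mask is true exactly where HU strictly exceeds *hu_threshold*
    (2500 by default, above the radiodensity of compact bone).
    """
    return BinaryVolume(
        mask=np.asarray(vol.values) > hu_threshold,
        spacing=vol.spacing,
        affine=vol.affine.copy(),
    )


def label_clusters(binary: BinaryVolume) -> ClusterLabeling:
    """Label connected components of the mask under 6-connectivity.

    Adjacency is through shared voxel faces only (not edges or corners).
    Cluster ids are assigned in scan order of each component's first
    voxel, so the labeling is deterministic across runs and platforms.
    """
    labels, n = ndi.label(binary.mask, structure=SIX_CONNECTIVITY)
    if n > 0:
        labels = _relabel_by_scan_order(labels, n)
    return ClusterLabeling(
        labels=labels,
        n_clusters=int(n),
        spacing=binary.spacing,
        affine=binary.affine.copy(),
    )


def _relabel_by_scan_order(labels: np.ndarray, n: int) -> np.ndarray:
    flat = labels.ravel()
    fg = np.flatnonzero(flat)
    # first occurrence (in raster-scan order) of each label value
    vals, first = np.unique(flat[fg], return_index=True)
    order = np.argsort(fg[first], kind="stable")
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[vals[order]] = np.arange(1, n + 1)
    return remap[labels]


def save_labelmap(labeling: ClusterLabeling, path: str | os.PathLike) -> None:
    """Write a cluster labeling as an integer NIfTI label map."""
    import nibabel as nib

    img = nib.Nifti1Image(labeling.labels.astype(np.int32), labeling.affine)
    img.header.set_zooms(labeling.spacing)
    nib.save(img, str(path))
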