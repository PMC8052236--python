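"""CT volume I/O and isotropic resampling.

Volumes are held in a canonical right-handed, axis-aligned frame
(``nibabel`` closest-canonical orientation) with values in Hounsfield
units. Resampling uses third-order spline interpolation on a
cell-centered grid anchored at the first voxel center of the input.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi

__all__ = ["CTVolume", "load_ct", "resample_isotropic", "save_nifti"]

#: Default isotropic voxel side after resampling, in mm.
DEFAULT_TARGET_SPACING = 0.5


class GeometryError(ValueError):
    """Raised when a volume's spatial metadata is unusable."""


@dataclass
class CTVolume:
    """A 3D radiodensity grid with voxel spacing and world geometry.

    Parameters
    ----------
    values
        3D array of Hounsfield-unit values, indexed ``[i, j, k]``.
    spacing
        Per-axis voxel size in mm (3 strictly positive floats).
    affine
        4x4 voxel-index -> world-mm homogeneous mapping. The column
        norms of its linear part must equal ``spacing``.
    source_id
        Free-text provenance tag.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError("values must be a 3D grid with >= 1 voxel per axis")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3:
            raise ValueError("spacing must have 3 entries")
        if not all(np.isfinite(s) and s > 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive and finite, got {self.spacing}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise GeometryError("affine is singular")
        col_norms = np.linalg.norm(self.affine[:3, :3], axis=0)
        if not np.allclose(col_norms, self.spacing, rtol=1e-6, atol=0.0):
            raise GeometryError(
                f"affine column norms {col_norms} do not match spacing {self.spacing}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to (n, 3) world-mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]


def load_ct(path: str | os.PathLike, format_hint: str | None = None) -> CTVolume:
    """Read a CT volume from a NIfTI file or a single-series DICOM directory.

    Values are returned in Hounsfield units (the DICOM rescale
    slope/intercept is applied) and the volume is reoriented to the
    closest canonical right-handed frame.

    Parameters
    ----------
    path
        A ``.nii``/``.nii.gz`` file or a directory of DICOM slices
        belonging to one series.
    format_hint
        ``"nifti"`` or ``"dicom_dir"``; inferred from the path when None.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    ValueError
        For a multi-series DICOM directory, non-monotonic slice
        positions, or an unrecognized format.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")
    if format_hint is None:
        format_hint = "dicom_dir" if path.is_dir() else "nifti"
    if format_hint == "nifti":
        return _load_nifti(path)
    if format_hint == "dicom_dir":
        return _load_dicom_dir(path)
    raise ValueError(f"unknown format_hint {format_hint!r}")


def _load_nifti(path: Path) -> CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    values = np.asarray(img.get_fdata(dtype=np.float32))
    if values.ndim == 4 and values.shape[3] == 1:
        values = values[..., 0]
    if values.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {values.shape}")
    affine = np.asarray(img.affine, dtype=float)
    spacing = tuple(np.linalg.norm(affine[:3, :3], axis=0))
    return CTVolume(values=values, spacing=spacing, affine=affine, source_id=str(path))


def _load_dicom_dir(path: Path) -> CTVolume:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading DICOM directories requires the optional 'pydicom' "
            "dependency (pip install ecogloc[dicom])"
        ) from exc

    files = sorted(p for p in path.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f), stop_before_pixels=False)
        except Exception:
            continue
        if hasattr(ds, "ImagePositionPatient") and hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no readable DICOM slices found in {path}")

    series = sorted({getattr(ds, "SeriesInstanceUID", "?") for ds in slices})
    if len(series) > 1:
        raise ValueError(
            f"directory {path} contains {len(series)} DICOM series: "
            + ", ".join(series)
        )

    orient = np.asarray(slices[0].ImageOrientationPatient, dtype=float)
    row_dir, col_dir = orient[:3], orient[3:]
    normal = np.cross(row_dir, col_dir)
    positions = np.array([np.dot(normal, ds.ImagePositionPatient) for ds in slices])
    order = np.argsort(positions)
    slices = [slices[i] for i in order]
    positions = positions[order]
    steps = np.diff(positions)
    if len(steps) and (steps.min() <= 0 or not np.allclose(steps, steps[0], rtol=1e-3)):
        raise GeometryError("non-monotonic or non-uniform DICOM slice positions")

    def hu(ds):
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        return ds.pixel_array.astype(np.float32) * slope + intercept

    # stack as [row, col, slice] then build the voxel->world affine
    values = np.stack([hu(ds) for ds in slices], axis=-1)
    ps = [float(v) for v in slices[0].PixelSpacing]  # (row, col) spacing
    dz = float(steps[0]) if len(steps) else float(
        getattr(slices[0], "SliceThickness", 1.0)
    )
    affine = np.eye(4)
    # pixel_array rows advance along col_dir spacing ps[0]; columns along row_dir
    affine[:3, 0] = col_dir * ps[0]
    affine[:3, 1] = row_dir * ps[1]
    affine[:3, 2] = normal * dz
    affine[:3, 3] = np.asarray(slices[0].ImagePositionPatient, dtype=float)
    vol = CTVolume(
        values=values,
        spacing=(ps[0], ps[1], dz),
        affine=affine,
        source_id=str(path),
    )
    return _to_canonical(vol)


def _to_canonical(vol: CTVolume) -> CTVolume:
    """Reorient to the nibabel closest-canonical (RAS-like) frame."""
    import nibabel as nib

    img = nib.Nifti1Image(vol.values, vol.affine)
    img = nib.as_closest_canonical(img)
    affine = np.asarray(img.affine, dtype=float)
    spacing = tuple(np.linalg.norm(affine[:3, :3], axis=0))
    return CTVolume(
        values=np.asarray(img.dataobj),
        spacing=spacing,
        affine=affine,
        source_id=vol.source_id,
    )


def resample_isotropic(
    vol: CTVolume,
    target_spacing: float = DEFAULT_TARGET_SPACING,
    *,
    order: int = 3,
    clamp: bool = False,
) -> CTVolume:
    """Resample a volume to cubic voxels of side *target_spacing* mm.

    The output grid is cell-centered and anchored at the input's first
    voxel center; the size per axis is ``floor(n_in * spacing_in /
    target)`` (minimum 1), so the sampled world extent is preserved to
    within one output voxel. Interpolation is a third-order spline;
    samples nominally outside the input take the nearest-edge value.

    Parameters
    ----------
    vol
        Input volume.
    target_spacing
        Desired isotropic voxel side in mm (> 0).
    order
        Spline order (3 = cubic, the default).
    clamp
        If True, clip interpolated values to the input's [min, max]
        range, suppressing spline overshoot near metal edges.
    """
    if not (np.isfinite(target_spacing) and target_spacing > 0):
        raise ValueError(f"target_spacing must be > 0, got {target_spacing}")
    spacing = np.asarray(vol.spacing, dtype=float)
    shape_in = np.asarray(vol.shape)
    # 1e-9 guards the floor against float round-off when the ratio is integral
    shape_out = np.maximum(
        np.floor(shape_in * spacing / target_spacing + 1e-9).astype(int), 1
    )
    scale = target_spacing / spacing  # output index -> input index factor

    if np.allclose(scale, 1.0, rtol=0, atol=1e-12) and np.all(shape_out == shape_in):
        values = np.array(vol.values, dtype=np.float32)
    else:
        values = ndi.affine_transform(
            np.asarray(vol.values, dtype=np.float32),
            np.diag(scale),
            output_shape=tuple(shape_out),
            order=order,
            mode="nearest",
            output=np.float32,
        )
    if clamp:
        np.clip(values, float(np.min(vol.values)), float(np.max(vol.values)), out=values)

    affine = vol.affine.copy()
    affine[:3, :3] = vol.affine[:3, :3] @ np.diag(scale)
    return CTVolume(
        values=values,
        spacing=(target_spacing,) * 3,
        affine=affine,
        source_id=vol.source_id,
    )


def save_nifti(vol: CTVolume, path: str | os.PathLike) -> None:
    """Write a volume (HU values and affine) to a NIfTI-1 file."""
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(vol.values, dtype=np.float32), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
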