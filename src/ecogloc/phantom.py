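"""Synthetic post-implant head-CT phantom with per-object ground truth.

The scene is an ellipsoidal head with a skull shell, disc electrodes
arranged in strips and grids tangent to a spherical placement surface
inside the skull, sleeve-contact depth arrays along straight insertion
lines, and wires / stitches / screws as distractor metal. Metal is
painted as fractional voxel occupancy (supersampled), mixed with the
anatomical background, convolved with a Gaussian point-spread function
and corrupted with additive Gaussian noise — reproducing the
partial-volume inflation of small dense objects that the shape
descriptors must tolerate.

Real platinum far exceeds the conventional 12-bit CT range, so the
default painted metal radiodensity (20000 HU, extended scale) is well
above the 2500 HU detection threshold even after blurring; this is what
makes thresholded electrode clusters come out larger than their nominal
size rather than eroded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from ecogloc.ct_io import CTVolume

__all__ = [
    "PhantomSpec",
    "GroundTruthObject",
    "GroundTruth",
    "MatchResult",
    "generate_phantom",
    "match_detections",
]

ECOG = "ECOG"
DEPTH = "DEPTH"
NON_ELECTRODE = "NON_ELECTRODE"

VALID_STRIPS = (4, 6, 8, 12)
VALID_GRIDS = ((8, 8), (6, 8))


class SceneGeometryError(ValueError):
    """Raised when an object cannot be placed inside the phantom grid."""


@dataclass
class PhantomSpec:
    """Scene description for one synthetic head CT.

    When ``spacing`` is None, the in-plane pixel size is drawn uniformly
    from [0.44, 0.98] mm with 0.625 mm slices; when ``grid_shape`` is
    None it is derived from the head radius plus an 8 mm margin.
    """

    grid_shape: tuple[int, int, int] | None = None
    spacing: tuple[float, float, float] | None = None
    head_radius: float = 65.0
    skull_hu: float = 1500.0
    metal_hu: float = 20000.0
    background_hu: float = 40.0
    psf_sigma: float = 0.4
    noise_sigma: float = 15.0
    strips: tuple[int, ...] = ()
    grids: tuple[tuple[int, int], ...] = ()
    electrode_diameter: float = 4.0
    electrode_thickness: float = 0.5
    electrode_spacing: float = 10.0
    n_wires: int = 0
    n_stitches: int = 0
    n_screws: int = 0
    depth_arrays: tuple[tuple[int, float, float, float], ...] = ()
    depth_fused: bool = False
    overlap_electrode_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "head_radius",
            "electrode_diameter",
            "electrode_thickness",
            "electrode_spacing",
            "psf_sigma",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for name in ("n_wires", "n_stitches", "n_screws", "overlap_electrode_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.electrode_spacing > self.electrode_diameter:
            raise ValueError("electrode_spacing must exceed electrode_diameter")
        for n in self.strips:
            if n < 2:
                raise ValueError(f"strip must have >= 2 electrodes, got {n}")
        for r, c in self.grids:
            if r < 2 or c < 2:
                raise ValueError(f"grid must be >= 2x2, got {(r, c)}")
        for n, length, diam, pitch in self.depth_arrays:
            if n < 1 or length <= 0 or diam <= 0 or pitch <= 0:
                raise ValueError("invalid depth array parameters")


@dataclass
class GroundTruthObject:
    object_id: int
    true_class: str
    centroid_mm: tuple[float, float, float]
    geometry: str


@dataclass
class GroundTruth:
    """One entry per generated metal object, with true class and centroid."""

    objects: list[GroundTruthObject]

    def __len__(self) -> int:
        return len(self.objects)

    def of_class(self, true_class: str) -> list[GroundTruthObject]:
        return [o for o in self.objects if o.true_class == true_class]

    def centroids(self, true_class: str | None = None) -> np.ndarray:
        objs = self.objects if true_class is None else self.of_class(true_class)
        return np.array([o.centroid_mm for o in objs], dtype=float).reshape(-1, 3)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "object_id": [o.object_id for o in self.objects],
                "class": [o.true_class for o in self.objects],
                "x_mm": [o.centroid_mm[0] for o in self.objects],
                "y_mm": [o.centroid_mm[1] for o in self.objects],
                "z_mm": [o.centroid_mm[2] for o in self.objects],
                "geometry": [o.geometry for o in self.objects],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# geometric primitives (painted as supersampled fractional occupancy)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    axis = _unit(axis)
    return (
        v * math.cos(angle)
        + np.cross(axis, v) * math.sin(angle)
        + axis * np.dot(axis, v) * (1.0 - math.cos(angle))
    )


def _orthonormal_tangents(u: np.ndarray, rng) -> tuple[np.ndarray, np.ndarray]:
    t = np.cross(u, rng.standard_normal(3))
    while np.linalg.norm(t) < 1e-8:
        t = np.cross(u, rng.standard_normal(3))
    t1 = _unit(t)
    return t1, _unit(np.cross(u, t1))


class _Painter:
    """Accumulates fractional metal occupancy on the acquisition grid."""

    #: offsets of the 3x3x3 supersampling stencil, in voxel units
    _SUB = np.array(
        np.meshgrid(*([[-1 / 3, 0.0, 1 / 3]] * 3), indexing="ij")
    ).reshape(3, -1).T

    def __init__(self, shape, spacing):
        self.occ = np.zeros(shape, dtype=np.float32)
        self.spacing = np.asarray(spacing, dtype=float)
        self.shape = np.asarray(shape)

    def _bbox_coords(self, lo_mm, hi_mm):
        lo = np.maximum(np.floor(lo_mm / self.spacing).astype(int) - 1, 0)
        hi = np.minimum(np.ceil(hi_mm / self.spacing).astype(int) + 2, self.shape)
        if np.any(hi <= lo):
            return None, None
        idx = np.stack(
            np.meshgrid(*[np.arange(lo[a], hi[a]) for a in range(3)], indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        return (lo, hi), idx

    def _paint(self, lo_mm, hi_mm, inside_fn):
        box, idx = self._bbox_coords(np.asarray(lo_mm), np.asarray(hi_mm))
        if box is None:
            return
        lo, hi = box
        pts = (idx[:, None, :] + self._SUB[None, :, :]) * self.spacing
        frac = inside_fn(pts.reshape(-1, 3)).reshape(len(idx), -1).mean(axis=1)
        view = self.occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        np.maximum(
            view, frac.reshape(hi[0] - lo[0], hi[1] - lo[1], hi[2] - lo[2]).astype(
                np.float32
            ),
            out=view,
        )

    def disc(self, center, normal, radius, half_thickness):
        center = np.asarray(center, dtype=float)
        normal = _unit(np.asarray(normal, dtype=float))
        pad = radius + half_thickness
        def inside(p):
            d = p - center
            ax = d @ normal
            rad2 = np.einsum("ij,ij->i", d, d) - ax**2
            return (np.abs(ax) <= half_thickness) & (rad2 <= radius**2)
        self._paint(center - pad, center + pad, inside)

    def cylinder(self, center, axis, radius, half_length):
        center = np.asarray(center, dtype=float)
        axis = _unit(np.asarray(axis, dtype=float))
        pad = radius + half_length
        def inside(p):
            d = p - center
            ax = d @ axis
            rad2 = np.einsum("ij,ij->i", d, d) - ax**2
            return (np.abs(ax) <= half_length) & (rad2 <= radius**2)
        self._paint(center - pad, center + pad, inside)

    def capsule(self, p0, p1, radius):
        p0 = np.asarray(p0, dtype=float)
        p1 = np.asarray(p1, dtype=float)
        seg = p1 - p0
        L2 = float(seg @ seg)
        def inside(p):
            d = p - p0
            t = np.clip((d @ seg) / L2 if L2 > 0 else 0.0, 0.0, 1.0)
            closest = p0 + t[:, None] * seg if L2 > 0 else p0
            r2 = np.einsum("ij,ij->i", p - closest, p - closest)
            return r2 <= radius**2
        self._paint(np.minimum(p0, p1) - radius, np.maximum(p0, p1) + radius, inside)

    def sphere(self, center, radius):
        center = np.asarray(center, dtype=float)
        def inside(p):
            d = p - center
            return np.einsum("ij,ij->i", d, d) <= radius**2
        self._paint(center - radius, center + radius, inside)


# ---------------------------------------------------------------------------
# scene generation


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, GroundTruth]:
    """Render a phantom head CT and its ground-truth object list.

    Deterministic given ``spec.seed``: the same spec produces
    bit-identical volumes and truths across runs.
    """
    rng = np.random.default_rng(spec.seed)

    if spec.spacing is None:
        px = float(rng.uniform(0.44, 0.98))
        spacing = np.array([px, px, 0.625])
    else:
        spacing = np.asarray(spec.spacing, dtype=float)
        rng.uniform(0.44, 0.98)  # keep the stream aligned across specs
    margin = 8.0
    world = 2.0 * (spec.head_radius + margin)
    if spec.grid_shape is None:
        shape = tuple(int(math.ceil(world / s)) for s in spacing)
    else:
        shape = tuple(spec.grid_shape)
    extent = np.asarray(shape) * spacing
    center = extent / 2.0

    # ellipsoidal head with a skull shell; electrodes sit on a sphere
    # comfortably inside the skull
    semi = spec.head_radius * np.array([1.0, 0.92, 0.85])
    r_surf = 0.78 * spec.head_radius
    if 2.0 * (semi.max() + 2.0) > extent.min():
        raise SceneGeometryError(
            f"head (radius {spec.head_radius} mm) does not fit in grid extent {extent}"
        )

    painter = _Painter(shape, spacing)
    truth: list[GroundTruthObject] = []
    electrode_centers: list[np.ndarray] = []
    distractor_centers: list[np.ndarray] = []
    oid = 0

    def _check_inside(pos, what):
        if np.any(pos < 1.0) or np.any(pos > extent - 1.0):
            raise SceneGeometryError(f"{what} at {pos} falls outside the volume")

    def add_disc(pos, normal, geometry):
        nonlocal oid
        _check_inside(pos, geometry)
        painter.disc(
            pos, normal, spec.electrode_diameter / 2.0, spec.electrode_thickness / 2.0
        )
        oid += 1
        truth.append(GroundTruthObject(oid, ECOG, tuple(pos), geometry))
        electrode_centers.append(np.asarray(pos, dtype=float))

    def _far_from(pos, centers, min_dist):
        if not centers:
            return True
        d = np.linalg.norm(np.asarray(centers) - pos, axis=1)
        return bool(d.min() >= min_dist)

    alpha = spec.electrode_spacing / r_surf  # great-circle step, radians

    # ---- ECoG grids ------------------------------------------------------
    for g_idx, (rows, cols) in enumerate(spec.grids):
        for attempt in range(800):
            u0 = _unit(rng.standard_normal(3))
            t1, t2 = _orthonormal_tangents(u0, rng)
            w1, w2 = np.cross(u0, t1), np.cross(u0, t2)
            offs_r = np.arange(rows) - (rows - 1) / 2.0
            offs_c = np.arange(cols) - (cols - 1) / 2.0
            centers = [
                center
                + r_surf
                * _rotate(_rotate(u0, w1, float(i) * alpha), w2, float(j) * alpha)
                for i in offs_r
                for j in offs_c
            ]
            if all(
                _far_from(c, electrode_centers, 0.8 * spec.electrode_spacing)
                for c in centers
            ):
                break
        else:
            raise SceneGeometryError(f"cannot place grid #{g_idx} of {rows}x{cols}")
        for e_idx, c in enumerate(centers):
            add_disc(c, c - center, f"grid{g_idx}[{e_idx}]")

    # ---- ECoG strips -----------------------------------------------------
    for s_idx, n_elec in enumerate(spec.strips):
        for attempt in range(800):
            u0 = _unit(rng.standard_normal(3))
            t1, _ = _orthonormal_tangents(u0, rng)
            w = np.cross(u0, t1)
            offs = np.arange(n_elec) - (n_elec - 1) / 2.0
            centers = [
                center + r_surf * _rotate(u0, w, float(o) * alpha) for o in offs
            ]
            if all(
                _far_from(c, electrode_centers, 0.8 * spec.electrode_spacing)
                for c in centers
            ):
                break
        else:
            raise SceneGeometryError(f"cannot place strip #{s_idx} of {n_elec}")
        for e_idx, c in enumerate(centers):
            add_disc(c, c - center, f"strip{s_idx}[{e_idx}]")

    # ---- deliberately overlapping electrode pairs ------------------------
    for p_idx in range(spec.overlap_electrode_pairs):
        for attempt in range(500):
            u0 = _unit(rng.standard_normal(3))
            pos = center + r_surf * u0
            if _far_from(pos, electrode_centers, 1.5 * spec.electrode_spacing):
                break
        else:
            raise SceneGeometryError(f"cannot place overlap pair #{p_idx}")
        t1, _ = _orthonormal_tangents(u0, rng)
        shift = 0.4 * spec.electrode_diameter * t1 + 0.6 * spec.electrode_thickness * u0
        add_disc(pos, u0, f"overlap{p_idx}[0]")
        add_disc(pos + shift, u0, f"overlap{p_idx}[1]")

    # ---- depth electrode arrays -----------------------------------------
    for a_idx, (n_contacts, c_len, c_diam, pitch) in enumerate(spec.depth_arrays):
        for attempt in range(500):
            u0 = _unit(rng.standard_normal(3))
            entry = center + r_surf * u0
            direction = _unit(center + rng.normal(0, 5.0, 3) - entry)
            centers = [entry + (2.0 + k * pitch) * direction for k in range(n_contacts)]
            if all(
                _far_from(c, electrode_centers, 0.8 * spec.electrode_spacing)
                for c in centers
            ):
                break
        else:
            raise SceneGeometryError(f"cannot place depth array #{a_idx}")
        for k, c in enumerate(centers):
            _check_inside(c, f"depth{a_idx}[{k}]")
            painter.cylinder(c, direction, c_diam / 2.0, c_len / 2.0)
            oid += 1
            truth.append(
                GroundTruthObject(oid, DEPTH, tuple(c), f"depth{a_idx}[{k}]")
            )
        if spec.depth_fused and n_contacts > 1:
            painter.capsule(centers[0], centers[-1], 0.4)

    # ---- wires (smooth random tubes, partly exiting the head) ------------
    for w_idx in range(spec.n_wires):
        for attempt in range(200):
            u0 = _unit(rng.standard_normal(3))
            start = center + float(rng.uniform(0.9, 1.05)) * spec.head_radius * u0
            direction = _unit(u0 + rng.normal(0, 0.5, 3))
            n_steps = int(rng.integers(30, 70))
            path = [start]
            for _ in range(n_steps):
                direction = _unit(direction + rng.normal(0, 0.12, 3))
                nxt = path[-1] + 1.0 * direction
                nxt = np.clip(nxt, 2.0, extent - 2.0)
                path.append(nxt)
            path = np.asarray(path)
            if all(_far_from(p, electrode_centers, 6.0) for p in path[::4]):
                break
        else:
            raise SceneGeometryError(f"cannot place wire #{w_idx}")
        radius = float(rng.uniform(0.8, 1.3)) / 2.0
        for p0, p1 in zip(path[:-1], path[1:]):
            painter.capsule(p0, p1, radius)
        oid += 1
        truth.append(
            GroundTruthObject(
                oid, NON_ELECTRODE, tuple(path.mean(axis=0)), f"wire{w_idx}"
            )
        )
        distractor_centers.append(path.mean(axis=0))

    # ---- stitches (short bent segments) ----------------------------------
    for s_idx in range(spec.n_stitches):
        for attempt in range(500):
            pos = rng.uniform(4.0, extent - 4.0)
            if _far_from(pos, electrode_centers, 6.0) and _far_from(
                pos, distractor_centers, 5.0
            ):
                break
        else:
            raise SceneGeometryError(f"cannot place stitch #{s_idx}")
        d1 = _unit(rng.standard_normal(3))
        kink = _unit(d1 + rng.normal(0, 0.7, 3))
        l1, l2 = rng.uniform(1.0, 2.5, 2)
        radius = float(rng.uniform(0.3, 0.5))
        mid = pos + l1 * d1
        painter.capsule(pos, mid, radius)
        painter.capsule(mid, mid + l2 * kink, radius)
        oid += 1
        truth.append(
            GroundTruthObject(oid, NON_ELECTRODE, tuple(mid), f"stitch{s_idx}")
        )
        distractor_centers.append(np.asarray(mid))

    # ---- screws (compact irregular blobs) --------------------------------
    for s_idx in range(spec.n_screws):
        for attempt in range(500):
            u0 = _unit(rng.standard_normal(3))
            pos = center + float(rng.uniform(0.95, 1.02)) * spec.head_radius * u0
            pos = np.clip(pos, 6.0, extent - 6.0)
            if _far_from(pos, electrode_centers, 8.0) and _far_from(
                pos, distractor_centers, 8.0
            ):
                break
        else:
            raise SceneGeometryError(f"cannot place screw #{s_idx}")
        size = float(rng.uniform(3.0, 8.0))
        painter.sphere(pos, 0.35 * size)
        for _ in range(int(rng.integers(2, 5))):
            off = rng.normal(0, 0.18 * size, 3)
            painter.sphere(pos + off, float(rng.uniform(0.2, 0.3)) * size)
        oid += 1
        truth.append(
            GroundTruthObject(oid, NON_ELECTRODE, tuple(pos), f"screw{s_idx}")
        )
        distractor_centers.append(np.asarray(pos))

    # ---- compose, blur, add noise ---------------------------------------
    axes_mm = [(np.arange(n) * s) for n, s in zip(shape, spacing)]
    rho2 = (
        ((axes_mm[0] - center[0]) / semi[0])[:, None, None] ** 2
        + ((axes_mm[1] - center[1]) / semi[1])[None, :, None] ** 2
        + ((axes_mm[2] - center[2]) / semi[2])[None, None, :] ** 2
    ).astype(np.float32)
    vol = np.full(shape, -1000.0, dtype=np.float32)
    vol[rho2 <= 1.0] = spec.skull_hu
    vol[rho2 <= 0.93**2] = spec.background_hu
    del rho2

    occ = painter.occ
    vol += occ * (spec.metal_hu - vol)
    del occ

    sigma_vox = spec.psf_sigma / spacing
    vol = ndi.gaussian_filter(vol, sigma=sigma_vox, mode="nearest")
    if spec.noise_sigma > 0:
        vol += spec.noise_sigma * rng.standard_normal(vol.shape, dtype=np.float32)

    affine = np.eye(4)
    affine[:3, :3] = np.diag(spacing)
    ct = CTVolume(
        values=vol,
        spacing=tuple(spacing),
        affine=affine,
        source_id=f"phantom-seed{spec.seed}",
    )
    return ct, GroundTruth(objects=truth)


# ---------------------------------------------------------------------------
# scoring detections against ground truth

TRUE_POSITIVE = "true_positive"
FALSE_NEGATIVE = "false_negative"
FALSE_POSITIVE = "false_positive"

ELECTRODE_CLASSES = (ECOG, DEPTH)


@dataclass
class MatchResult:
    """Outcome of matching per-cluster detections to ground truth."""

    matches: list[tuple[int, int]]  # (truth object_id, detection index)
    truth_outcomes: dict[int, str]  # truth object_id -> TP / FN
    detection_outcomes: dict[int, str]  # detection index -> TP / FP
    sensitivity: dict[str, float]  # per electrode class, %


def match_detections(
    predicted_classes,
    centroids_mm,
    truth: GroundTruth,
    tolerance_mm: float = 2.0,
) -> MatchResult:
    """Greedy one-to-one nearest-centroid matching within a tolerance.

    Detections and truth objects are matched per electrode class
    (closest pairs first). Unmatched truth electrodes count as false
    negatives; unmatched electrode-class detections as false positives.
    """
    if not tolerance_mm > 0:
        raise ValueError("tolerance_mm must be > 0")
    predicted_classes = np.asarray(predicted_classes, dtype=object)
    centroids_mm = np.asarray(centroids_mm, dtype=float).reshape(-1, 3)
    if len(predicted_classes) != len(centroids_mm):
        raise ValueError("predicted_classes and centroids_mm differ in length")

    matches: list[tuple[int, int]] = []
    truth_outcomes: dict[int, str] = {}
    detection_outcomes: dict[int, str] = {}
    sensitivity: dict[str, float] = {}

    for cls in ELECTRODE_CLASSES:
        t_objs = truth.of_class(cls)
        d_idx = np.flatnonzero(predicted_classes == cls)
        if len(t_objs) and len(d_idx):
            t_cent = np.array([o.centroid_mm for o in t_objs])
            dist = np.linalg.norm(
                t_cent[:, None, :] - centroids_mm[d_idx][None, :, :], axis=2
            )
            pairs = sorted(
                (
                    (dist[i, j], i, j)
                    for i in range(len(t_objs))
                    for j in range(len(d_idx))
                    if dist[i, j] <= tolerance_mm
                ),
            )
            used_t, used_d = set(), set()
            for _, i, j in pairs:
                if i in used_t or j in used_d:
                    continue
                used_t.add(i)
                used_d.add(j)
                matches.append((t_objs[i].object_id, int(d_idx[j])))
        else:
            used_t, used_d = set(), set()
        for i, o in enumerate(t_objs):
            truth_outcomes[o.object_id] = (
                TRUE_POSITIVE if i in used_t else FALSE_NEGATIVE
            )
        for j, di in enumerate(d_idx):
            detection_outcomes[int(di)] = (
                TRUE_POSITIVE if j in used_d else FALSE_POSITIVE
            )
        sensitivity[cls] = (
            100.0 * len(used_t) / len(t_objs) if t_objs else float("nan")
        )

    return MatchResult(
        matches=matches,
        truth_outcomes=truth_outcomes,
        detection_outcomes=detection_outcomes,
        sensitivity=sensitivity,
    )
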