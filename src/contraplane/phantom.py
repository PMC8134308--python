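"""Synthetic ankle phantoms with exact ground-truth standard-plane frames.

Real intra-operative C-arm volumes are not publicly available, so every
geometric stage of the pipeline is exercised on a minimal analytic phantom.
The canonical (right-ankle) template, expressed in the canonical frame
(intersection point at the origin, sagittal normal x̂, axial normal ŷ,
coronal normal ẑ), consists of:

* a large tube along ŷ (tibia shaft surrogate, radius 9 mm),
* a brighter transverse slab terminating the tube (tibial plafond; its
  lowest central point is the intersection point),
* a thinner parallel tube offset along +ẑ (fibula surrogate),
* an ellipsoid below the slab (talus surrogate), and
* a small bright knob on the +x̂ side (medial-malleolus surrogate) that
  makes the template chiral, so laterality is determined by the image.

A left ankle is the mirror image of the template (reflection of the
canonical z-axis), which flips the coronal normal and the frame handedness.
Each rendered ankle is scaled (default range 0.8–1.2), rotated per axis
(default ±45°), translated, and overlaid with additive Gaussian noise.
Ground-truth frames are the exactly transformed canonical frames, never
derived from the rendered voxels.

The module also provides the training-time augmentation (rotation / scale /
mirror / random crop, images trilinear, labels nearest-neighbor, frames
analytic) and the volume preprocessing (downsampling plus zero-mean /
unit-variance normalization) applied before network inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConstantVolumeWarning, PatchSizeError, PlacementError
from .geometry import ScalarVolume, StandardPlaneFrame, VolumeGrid, rotation_matrix
from .masks import CylinderMaskSpec, PlaneLabelVolume, SphereMaskSpec, make_plane_cylinder_masks, make_sphere_mask

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "generate_phantom",
    "augment",
    "AugmentResult",
    "preprocess",
    "DEFAULT_UNILATERAL_GRID",
    "DEFAULT_BILATERAL_GRID",
]

#: desk-scale default grids (paper-scale preprocessing would be 160³ at 0.96 mm)
DEFAULT_UNILATERAL_GRID = VolumeGrid((64, 64, 64), (1.5, 1.5, 1.5), (0.0, 0.0, 0.0))
DEFAULT_BILATERAL_GRID = VolumeGrid((72, 72, 72), (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))

_MARGIN_MM = 20.0  # minimum distance of an intersection point from the volume boundary
_MIN_SEPARATION_MM = 60.0  # minimum center separation of the two ankles


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters; a fixed seed makes the output bit-reproducible."""

    grid: VolumeGrid = DEFAULT_UNILATERAL_GRID
    n_ankles: int = 1
    rotation_range_deg: float = 45.0
    scale_range: tuple[float, float] = (0.8, 1.2)
    noise_sd: float = 0.05
    seed: int = 0
    mask_radius_mm: float = 25.0
    mask_height_mm: float = 2.0
    sphere_radius_mm: float = 5.0
    symmetric: bool = False  # bilateral only: right ankle is the exact mirror of the left

    def __post_init__(self):
        if self.n_ankles not in (1, 2):
            raise ValueError("n_ankles must be 1 or 2")
        if not (self.scale_range[0] < self.scale_range[1]):
            raise ValueError("scale_range must satisfy low < high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class PhantomSample:
    """A rendered phantom plus its exact ground truth."""

    volume: ScalarVolume
    frames: list[StandardPlaneFrame]
    lateralities: list[str]
    sphere_masks: list[np.ndarray]
    plane_masks: list[PlaneLabelVolume]
    spec: PhantomSpec | None = None
    scales: list[float] | None = None  # per-ankle template scale actually drawn


# --- canonical template -------------------------------------------------------

_TIBIA_RADIUS = 9.0
_PLATEAU_RADIUS = 12.0
_PLATEAU_HEIGHT = 3.0
_FIBULA_RADIUS = 4.0
_FIBULA_Z = 16.0
_SHAFT_TOP = 45.0
_KNOB_CENTER = np.array([13.0, 2.0, 0.0])
_KNOB_RADIUS = 5.0


def _template_intensity(c: np.ndarray) -> np.ndarray:
    """Intensity of the canonical right-ankle template at canonical coords c (..., 3)."""
    x, y, z = c[..., 0], c[..., 1], c[..., 2]
    out = np.zeros(x.shape, dtype=np.float32)
    r2_xz = x**2 + z**2
    tibia = (r2_xz <= _TIBIA_RADIUS**2) & (y >= _PLATEAU_HEIGHT) & (y <= _SHAFT_TOP)
    np.maximum(out, np.where(tibia, 1.0, 0.0), out=out)
    plateau = (r2_xz <= _PLATEAU_RADIUS**2) & (y >= 0.0) & (y <= _PLATEAU_HEIGHT)
    np.maximum(out, np.where(plateau, 1.4, 0.0), out=out)
    fibula = (x**2 + (z - _FIBULA_Z) ** 2 <= _FIBULA_RADIUS**2) & (y >= -10.0) & (y <= _SHAFT_TOP)
    np.maximum(out, np.where(fibula, 1.0, 0.0), out=out)
    talus = (x / 10.0) ** 2 + ((y + 9.0) / 6.0) ** 2 + (z / 10.0) ** 2 <= 1.0
    np.maximum(out, np.where(talus, 0.8, 0.0), out=out)
    knob = np.sum((c - _KNOB_CENTER) ** 2, axis=-1) <= _KNOB_RADIUS**2
    np.maximum(out, np.where(knob, 1.2, 0.0), out=out)
    return out


_MIRROR_Z = np.diag([1.0, 1.0, -1.0])


def _render_ankle(grid: VolumeGrid, center_mm, rotation: np.ndarray, scale: float, laterality: str) -> np.ndarray:
    """Render one ankle: world → canonical coords, then evaluate the template."""
    mirror = _MIRROR_Z if laterality == "left" else np.eye(3)
    coords = grid.world_coordinates() - np.asarray(center_mm, float)
    # w = t + s·R·M·c  ⇒  c = M·Rᵀ·(w − t)/s  (M is its own inverse)
    canon = coords @ (rotation @ mirror) / scale  # row-vector form of (M Rᵀ w)/s
    return _template_intensity(canon)


def _pose_frame(center_mm, rotation: np.ndarray, laterality: str) -> StandardPlaneFrame:
    mirror = _MIRROR_Z if laterality == "left" else np.eye(3)
    cols = rotation @ mirror
    return StandardPlaneFrame(np.asarray(center_mm, float), cols[:, 0], cols[:, 1], cols[:, 2])


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render a unilateral or bilateral phantom with exact ground truth.

    Bilateral samples contain one left and one right ankle whose
    intersection points are separated by more than 60 mm and keep a 20 mm
    margin from the volume boundary; placement is retried a bounded number
    of times before raising :class:`PlacementError`.
    """
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    extent = np.asarray(grid.extent_mm)
    origin = np.asarray(grid.origin_mm)
    lo = origin - 0.5 * np.asarray(grid.spacing_mm) + _MARGIN_MM
    hi = origin - 0.5 * np.asarray(grid.spacing_mm) + extent - _MARGIN_MM
    if np.any(hi <= lo):
        raise PlacementError(f"grid extent {tuple(extent)} mm cannot hold a {_MARGIN_MM} mm margin")

    def sample_pose():
        angles = rng.uniform(-spec.rotation_range_deg, spec.rotation_range_deg, size=3)
        scale = rng.uniform(*spec.scale_range)
        return rotation_matrix(angles), float(scale)

    if spec.n_ankles == 1:
        laterality = "left" if rng.random() < 0.5 else "right"
        rotation, scale = sample_pose()
        center = rng.uniform(lo, hi)
        placements = [(center, rotation, scale, laterality)]
    else:
        # one ankle per x-half; left-laterality side randomized
        sides = ["left", "right"] if rng.random() < 0.5 else ["right", "left"]
        mid = (lo[0] + hi[0]) / 2.0
        for _ in range(50):
            c0 = rng.uniform([lo[0], lo[1], lo[2]], [mid, hi[1], hi[2]])
            if spec.symmetric:
                c1 = np.array([lo[0] + hi[0] - c0[0], c0[1], c0[2]])
            else:
                c1 = rng.uniform([mid, lo[1], lo[2]], [hi[0], hi[1], hi[2]])
            if np.linalg.norm(c1 - c0) > _MIN_SEPARATION_MM:
                break
        else:
            raise PlacementError("could not place two ankles with >60 mm separation")
        rotation0, scale0 = sample_pose()
        if spec.symmetric:
            # mirror the whole pose of ankle 0 across the world x mid-plane
            mx = np.diag([-1.0, 1.0, 1.0])
            rotation1, scale1 = mx @ rotation0 @ _MIRROR_Z, scale0
            # rotation1 maps the opposite-laterality template to the mirrored pose:
            # (Mx R Mz) Mz' with Mz' from the flipped laterality reproduces Mx R.
        else:
            rotation1, scale1 = sample_pose()
        placements = [(c0, rotation0, scale0, sides[0]), (c1, rotation1, scale1, sides[1])]

    values = np.zeros(grid.shape, dtype=np.float32)
    frames, lateralities, sphere_masks, plane_masks, scales = [], [], [], [], []
    for center, rotation, scale, laterality in placements:
        scales.append(float(scale))
        values = np.maximum(values, _render_ankle(grid, center, rotation, scale, laterality))
        frame = _pose_frame(center, rotation, laterality)
        frames.append(frame)
        lateralities.append(laterality)
        sphere_masks.append(make_sphere_mask(SphereMaskSpec(tuple(center), spec.sphere_radius_mm), grid))
        plane_masks.append(
            make_plane_cylinder_masks(
                CylinderMaskSpec(frame, spec.mask_radius_mm, spec.mask_height_mm), grid
            )
        )
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, size=values.shape).astype(np.float32)
    return PhantomSample(
        ScalarVolume(grid, values), frames, lateralities, sphere_masks, plane_masks, spec, scales
    )


# --- augmentation -------------------------------------------------------------


@dataclass
class AugmentResult:
    volume: ScalarVolume
    targets: list[np.ndarray]
    frames: list[StandardPlaneFrame]
    angles_deg: tuple[float, float, float]
    scale: float
    mirror_axis: int | None
    crop_start: tuple[int, int, int]


def augment(
    volume: ScalarVolume,
    targets: list[np.ndarray] | None = None,
    frames: list[StandardPlaneFrame] | None = None,
    seed: int | None = None,
    *,
    angles_deg=None,
    scale: float | None = None,
    mirror_axis: int | None = -1,
    crop_size: int | None = None,
    crop_start=None,
    rotation_range_deg: float = 45.0,
    scale_range: tuple[float, float] = (0.8, 1.2),
    mirror_prob: float = 0.5,
) -> AugmentResult:
    """One online-augmentation draw: rotate, scale, mirror, random-crop.

    The same geometric transform is applied to the image (trilinear), to the
    label targets (nearest-neighbor) and to the ground-truth frames
    (analytically, never by resampling).  Explicit ``angles_deg`` / ``scale``
    / ``mirror_axis`` (None = no mirror) / ``crop_start`` override sampling;
    ``mirror_axis=-1`` requests sampling.  Rotation, scale and mirror act
    about/through the input volume's center.
    """
    rng = np.random.default_rng(seed)
    grid = volume.grid
    if angles_deg is None:
        angles_deg = tuple(rng.uniform(-rotation_range_deg, rotation_range_deg, size=3))
    if scale is None:
        scale = float(rng.uniform(*scale_range))
    if mirror_axis == -1:
        mirror_axis = int(rng.integers(0, 3)) if rng.random() < mirror_prob else None
    if crop_size is None:
        crop_size = min(grid.shape)
    if any(crop_size > s for s in grid.shape):
        raise PatchSizeError(f"crop size {crop_size} exceeds volume shape {grid.shape}")
    if crop_start is None:
        crop_start = tuple(int(rng.integers(0, s - crop_size + 1)) for s in grid.shape)
    else:
        crop_start = tuple(int(c) for c in crop_start)

    rot = rotation_matrix(angles_deg)
    mirror = np.eye(3)
    if mirror_axis is not None:
        mirror[mirror_axis, mirror_axis] = -1.0
    center = grid.center_mm
    # forward map T(p) = c + M·R·s·(p − c); sample input at T⁻¹(w) = c + Rᵀ·M·(w − c)/s
    inv_lin = rot.T @ mirror / scale

    out_grid = VolumeGrid(
        (crop_size,) * 3,
        grid.spacing_mm,
        tuple(np.asarray(grid.origin_mm) + np.asarray(crop_start) * np.asarray(grid.spacing_mm)),
    )
    w_out = out_grid.world_coordinates()
    p_in = (w_out - center) @ inv_lin.T + center
    idx = (p_in - np.asarray(grid.origin_mm)) / np.asarray(grid.spacing_mm)
    # snap to the lattice where rounding noise is the only offset, so identity
    # and pure-mirror transforms reproduce voxel values exactly
    snapped = np.round(idx)
    idx = np.where(np.abs(idx - snapped) < 1e-9, snapped, idx)
    coords = np.moveaxis(idx, -1, 0)
    out_values = ndimage.map_coordinates(
        volume.values.astype(np.float32), coords, order=1, mode="constant", cval=0.0
    )
    out_targets = []
    for t in targets or []:
        arr = t.labels if isinstance(t, PlaneLabelVolume) else np.asarray(t)
        out_targets.append(
            ndimage.map_coordinates(arr, coords, order=0, mode="constant", cval=0).astype(arr.dtype)
        )
    fwd = mirror @ rot  # applied to directions; scale cancels on unit normals
    out_frames = []
    for f in frames or []:
        p = center + (mirror @ rot) @ (scale * (f.intersection_mm - center))
        cols = fwd @ f.matrix
        out_frames.append(StandardPlaneFrame(p, cols[:, 0], cols[:, 1], cols[:, 2]))
    return AugmentResult(
        ScalarVolume(out_grid, out_values),
        out_targets,
        out_frames,
        tuple(float(a) for a in angles_deg),
        float(scale),
        mirror_axis,
        crop_start,
    )


# --- preprocessing ------------------------------------------------------------


def preprocess(volume: ScalarVolume, target_shape) -> ScalarVolume:
    """Downsample to ``target_shape`` per axis and normalize to mean 0, var 1.

    Trilinear resampling with the voxel-center ("half-pixel") alignment that
    preserves the physical extent: the new spacing is
    ``spacing · old_shape / new_shape`` and the volume center is unchanged.
    A constant input cannot be variance-normalized; it yields a zero volume
    and a :class:`ConstantVolumeWarning`.
    """
    if np.isscalar(target_shape):
        target_shape = (int(target_shape),) * 3
    grid = volume.grid
    factors = np.asarray(grid.shape) / np.asarray(target_shape)
    new_spacing = tuple(s * f for s, f in zip(grid.spacing_mm, factors))
    new_origin = tuple(
        o + 0.5 * (ns - s) for o, s, ns in zip(grid.origin_mm, grid.spacing_mm, new_spacing)
    )
    axes = [(np.arange(n) * f + (f - 1) / 2.0) for n, f in zip(target_shape, factors)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    values = ndimage.map_coordinates(
        volume.values.astype(np.float64), np.stack([gx, gy, gz]), order=1, mode="nearest"
    )
    sd = float(values.std())
    if sd == 0.0:
        warnings.warn("constant volume: normalization undefined, returning zeros", ConstantVolumeWarning)
        out = np.zeros(target_shape, dtype=np.float32)
    else:
        out = ((values - values.mean()) / sd).astype(np.float32)
    return ScalarVolume(VolumeGrid(tuple(target_shape), new_spacing, new_origin), out)
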