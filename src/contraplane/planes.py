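"""Stage 2 — ROI cropping, cylinder-mask PCA and standard-plane recovery.

Each detected ankle is cropped to a cube centered on its plateau landmark.
A 4-class segmenter (trained U-Net or oracle) labels the three plane
cylinders; principal component analysis of each class's voxel coordinates
recovers the plane parameters: the two largest eigenvalues span the
cylinder disc, and the eigenvector of the smallest eigenvalue is the plane
normal.  The intersection point is taken as the mean of the three class
centroids, and the three raw normals are reconciled into an exactly
orthonormal frame.  The central cross-bars omitted from the training masks
are symmetric about the plane, so their absence barely biases either the
PCA or the centroid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .errors import EigenvalueDegeneracyWarning, InsufficientForegroundError, MissingClassError
from .geometry import ScalarVolume, StandardPlaneFrame, VolumeGrid, orthonormalize_frame, voxel_to_world, world_to_voxel
from .masks import LABEL_NAMES, PlaneLabelVolume

__all__ = ["RoiCrop", "PlaneEstimate", "crop_roi", "derive_plane_params", "estimate_frame", "estimate_planes"]

#: reference directions used for sign disambiguation when no frame is given
CANONICAL_DIRECTIONS = {
    "sagittal": np.array([1.0, 0.0, 0.0]),
    "axial": np.array([0.0, 1.0, 0.0]),
    "coronal": np.array([0.0, 0.0, 1.0]),
}


@dataclass
class RoiCrop:
    """A cube cropped around a detection, with exact world bookkeeping.

    The cropped grid's origin is shifted so each cropped voxel has the same
    world coordinate as its parent voxel; out-of-parent regions are zero
    filled and flagged in ``pad_mask``.
    """

    volume: ScalarVolume
    offset_voxels: tuple[int, int, int]
    parent_grid: VolumeGrid
    pad_mask: np.ndarray


@dataclass
class PlaneEstimate:
    """Recovered frame plus the per-class PCA diagnostics."""

    frame: StandardPlaneFrame
    per_class_voxel_counts: tuple[int, int, int]
    eigenvalue_triples: tuple[tuple[float, float, float], ...]
    degenerate_classes: tuple[str, ...] = ()


def crop_roi(volume: ScalarVolume, center_mm, size_voxels: int) -> RoiCrop:
    """Crop a ``size_voxels``³ cube centered on the voxel nearest ``center_mm``.

    Regions outside the parent volume are zero-padded and recorded in the
    pad mask.  The center must lie inside the parent grid.
    """
    if size_voxels < 16:
        raise ValueError("size_voxels must be ≥ 16")
    grid = volume.grid
    if not grid.contains_world(center_mm):
        raise ValueError(f"crop center {center_mm} lies outside the parent grid")
    center_vox = np.round(world_to_voxel(center_mm, grid)).astype(int)
    start = center_vox - size_voxels // 2
    stop = start + size_voxels

    out = np.zeros((size_voxels,) * 3, dtype=volume.values.dtype)
    pad = np.ones((size_voxels,) * 3, dtype=bool)
    src = tuple(slice(max(a, 0), min(b, n)) for a, b, n in zip(start, stop, grid.shape))
    dst = tuple(
        slice(s.start - a, s.stop - a) for s, a in zip(src, start)
    )
    if all(s.stop > s.start for s in src):
        out[dst] = volume.values[src]
        pad[dst] = False
    crop_grid = VolumeGrid((size_voxels,) * 3, grid.spacing_mm, tuple(voxel_to_world(start, grid)))
    return RoiCrop(ScalarVolume(crop_grid, out), tuple(int(s) for s in start), grid, pad)


def derive_plane_params(
    class_mask: np.ndarray,
    grid: VolumeGrid,
    reference_direction=None,
    min_voxels: int = 50,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    """PCA of one cylinder class: (unit normal, centroid mm, eigenvalues desc).

    The normal is the eigenvector of the smallest covariance eigenvalue (the
    two large eigenvalues span the cylinder disc).  The returned normal is
    flipped to have a non-negative dot product with ``reference_direction``
    when one is supplied.  An :class:`EigenvalueDegeneracyWarning` is issued
    when the eigengap ``(λ2 − λ3)/λ1`` falls below 0.05 — the disc and
    thickness directions are then barely distinguishable.
    """
    fg = np.argwhere(np.asarray(class_mask))
    if fg.shape[0] < min_voxels:
        raise InsufficientForegroundError(
            f"class mask has {fg.shape[0]} voxels, fewer than min_voxels={min_voxels}"
        )
    coords = voxel_to_world(fg, grid)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    cov = centered.T @ centered / coords.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    normal = eigvecs[:, 0]
    eigvals_desc = tuple(float(v) for v in eigvals[::-1])
    if (eigvals_desc[1] - eigvals_desc[2]) / max(eigvals_desc[0], 1e-30) < 0.05:
        warnings.warn(
            "small eigengap between in-plane and normal directions; normal may be unreliable",
            EigenvalueDegeneracyWarning,
        )
    if reference_direction is not None and float(normal @ np.asarray(reference_direction)) < 0:
        normal = -normal
    return normal, centroid, eigvals_desc


def estimate_frame(
    label_volume: PlaneLabelVolume,
    reference: StandardPlaneFrame | None = None,
    min_voxels: int = 50,
    intersection_mode: str = "centroid-mean",
) -> PlaneEstimate:
    """Recover the standard-plane frame from a 4-class cylinder segmentation.

    Per-class PCA supplies one raw normal per plane; the intersection point
    is the unweighted mean of the three class centroids (robust to the
    unequal class sizes left by the intersection-omission rule; set
    ``intersection_mode="pooled"`` for the mean over all foreground voxels
    instead).  Raw normals are sign-disambiguated against ``reference`` (or
    the canonical axes) and reconciled by nearest-orthonormal projection.
    """
    if intersection_mode not in ("centroid-mean", "pooled"):
        raise ValueError("intersection_mode must be 'centroid-mean' or 'pooled'")
    labels = label_volume.labels
    grid = label_volume.grid
    normals, centroids, eigs, counts, degenerate = [], [], [], [], []
    for k, name in LABEL_NAMES.items():
        mask = labels == k
        count = int(mask.sum())
        if count < min_voxels:
            raise MissingClassError(name)
        ref_dir = reference.normals[name] if reference is not None else CANONICAL_DIRECTIONS[name]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", EigenvalueDegeneracyWarning)
            normal, centroid, ev = derive_plane_params(mask, grid, ref_dir, min_voxels)
        if any(issubclass(w.category, EigenvalueDegeneracyWarning) for w in caught):
            degenerate.append(name)
            warnings.warn(f"{name}: small PCA eigengap", EigenvalueDegeneracyWarning)
        normals.append(normal)
        centroids.append(centroid)
        eigs.append(ev)
        counts.append(count)
    if intersection_mode == "centroid-mean":
        intersection = np.mean(centroids, axis=0)
    else:
        fg = np.argwhere(labels > 0)
        intersection = voxel_to_world(fg, grid).mean(axis=0)
    frame = orthonormalize_frame(np.stack(normals, axis=1), intersection)
    return PlaneEstimate(frame, tuple(counts), tuple(eigs), tuple(degenerate))


def estimate_planes(
    roi: RoiCrop,
    segmenter: Callable[[ScalarVolume], PlaneLabelVolume],
    reference: StandardPlaneFrame | None = None,
    min_voxels: int = 50,
    intersection_mode: str = "centroid-mean",
) -> PlaneEstimate:
    """Segment an ROI and recover its frame in parent-volume world coordinates.

    ``segmenter`` maps the ROI volume to a :class:`PlaneLabelVolume` on the
    same grid (trained network or oracle; any intensity normalization is the
    segmenter's own concern).  Because the crop grid preserves world
    coordinates, the recovered frame already lives in the parent volume's
    coordinate system.
    """
    label_volume = segmenter(roi.volume)
    if tuple(label_volume.grid.shape) != tuple(roi.volume.grid.shape):
        raise ValueError("segmenter returned labels on a different grid than the ROI")
    return estimate_frame(label_volume, reference, min_voxels, intersection_mode)
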