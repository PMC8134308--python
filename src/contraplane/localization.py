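"""Stage 1 — tibia-plateau localization by patch fusion and weighted k-means.

The localizer network (or the oracle test double) scores each voxel of a
sliding-window patch with a foreground probability for the 5 mm landmark
sphere.  Overlapping patch predictions are fused by per-voxel arithmetic
mean, and the plateau center(s) are extracted from the fused map by a
weighted k-means in world-mm coordinates, using the fused probabilities as
weights so stray false-positive voxels barely move the centers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import DuplicateDetectionWarning, InsufficientForegroundError, NonConvergenceWarning, PatchSizeError
from .geometry import ScalarVolume, VolumeGrid, voxel_to_world

__all__ = [
    "ProbabilityMap",
    "AnkleDetection",
    "extract_patches",
    "fuse_predictions",
    "weighted_kmeans",
    "localize",
]


@dataclass
class ProbabilityMap:
    """Per-voxel foreground score in [0, 1] on the source grid."""

    grid: VolumeGrid
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if tuple(self.values.shape) != tuple(self.grid.shape):
            raise ValueError("values shape does not match grid shape")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("probability values must lie in [0, 1]")


@dataclass
class AnkleDetection:
    """One localized plateau center with its supporting cluster mass."""

    center_mm: np.ndarray
    total_weight: float
    member_voxel_count: int
    merged: bool = False

    def to_dict(self) -> dict:
        return {
            "center_mm": [float(x) for x in self.center_mm],
            "total_weight": float(self.total_weight),
            "member_voxel_count": int(self.member_voxel_count),
            "merged": bool(self.merged),
        }


def extract_patches(volume: ScalarVolume, patch_size: int, stride: int) -> list[tuple[ScalarVolume, tuple[int, int, int]]]:
    """Overlapping sliding-window patches covering every voxel at least once.

    Offsets form the stride lattice per axis; the final offset is clamped so
    the last patch ends flush with the volume boundary (no zero-padding, all
    predictions are made on real image content).  Each patch is returned as
    a :class:`ScalarVolume` whose grid carries the correct world origin, so
    geometry-aware predictors (the oracle) can be used interchangeably with
    intensity-only ones (the network).
    """
    if stride < 1:
        raise ValueError("stride must be ≥ 1")
    grid = volume.grid
    if any(patch_size > s for s in grid.shape):
        raise PatchSizeError(f"patch size {patch_size} exceeds volume shape {grid.shape}")
    offsets_per_axis = []
    for n in grid.shape:
        offs = list(range(0, n - patch_size + 1, stride))
        if offs[-1] != n - patch_size:
            offs.append(n - patch_size)
        offsets_per_axis.append(offs)
    patches = []
    for ox in offsets_per_axis[0]:
        for oy in offsets_per_axis[1]:
            for oz in offsets_per_axis[2]:
                off = (ox, oy, oz)
                sub = volume.values[ox : ox + patch_size, oy : oy + patch_size, oz : oz + patch_size]
                sub_grid = VolumeGrid(
                    (patch_size,) * 3,
                    grid.spacing_mm,
                    tuple(voxel_to_world(off, grid)),
                )
                patches.append((ScalarVolume(sub_grid, sub.copy()), off))
    return patches


def fuse_predictions(
    patch_preds: Sequence[tuple[np.ndarray, tuple[int, int, int]]], out_grid: VolumeGrid
) -> ProbabilityMap:
    """Per-voxel arithmetic mean of all patch predictions covering the voxel.

    Patches are accumulated in a canonical order (sorted by offset) with
    compensated (Kahan) summation, so the fused map is exactly invariant to
    the order in which patches are supplied.  Every voxel must be covered by
    at least one patch.
    """
    acc = np.zeros(out_grid.shape, dtype=np.float64)
    comp = np.zeros(out_grid.shape, dtype=np.float64)
    count = np.zeros(out_grid.shape, dtype=np.int32)
    for pred, off in sorted(patch_preds, key=lambda item: tuple(item[1])):
        pred = np.asarray(pred, dtype=np.float64)
        sl = tuple(slice(o, o + s) for o, s in zip(off, pred.shape))
        region = acc[sl]
        if region.shape != pred.shape:
            raise ValueError(f"patch at offset {off} with shape {pred.shape} does not fit the grid")
        # Kahan step
        y = pred - comp[sl]
        t = region + y
        comp[sl] = (t - region) - y
        acc[sl] = t
        count[sl] += 1
    if np.any(count == 0):
        raise ValueError("fuse_predictions: some voxels are covered by no patch")
    values = acc / count
    return ProbabilityMap(out_grid, np.clip(values, 0.0, 1.0))


def weighted_kmeans(
    prob_map: ProbabilityMap,
    k: int,
    seed: int = 0,
    weight_floor: float = 0.05,
    max_iter: int = 100,
    merge_distance_mm: float = 40.0,
) -> list[AnkleDetection]:
    """Weighted k-means on the world-mm coordinates of supra-floor voxels.

    Voxels with fused probability ≤ ``weight_floor`` are excluded; the rest
    enter with their probability as weight.  Initialization is deterministic
    farthest-point seeding from the weight-maximum voxel.  Assignment is by
    nearest center (ties to the lower center index); the update is the
    weighted mean of the assigned voxels.  Detections are sorted by
    descending total weight, then by x.  If the two k=2 centers converge
    closer than ``merge_distance_mm`` they are merged into a single
    detection with a warning (a duplicate of one ankle, not two ankles).
    """
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    mask = prob_map.values > weight_floor
    n_fg = int(mask.sum())
    if n_fg < k:
        raise InsufficientForegroundError(
            f"only {n_fg} voxels above weight floor {weight_floor}, need ≥ {k}"
        )
    idx = np.argwhere(mask)
    weights = prob_map.values[mask]
    coords = voxel_to_world(idx, prob_map.grid)

    # deterministic farthest-point initialization
    flat_order = np.lexsort(idx.T[::-1])  # C-order tie-break
    w_sorted = weights[flat_order]
    start = flat_order[int(np.argmax(w_sorted))]
    centers = [coords[start]]
    if k == 2:
        d = np.linalg.norm(coords - centers[0], axis=1)
        far = flat_order[int(np.argmax(d[flat_order]))]
        centers.append(coords[far])
    centers = np.array(centers, dtype=float)

    assignment = None
    converged = False
    for _ in range(max_iter):
        d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_assignment = np.argmin(d2, axis=1)  # argmin takes the lower index on ties
        new_centers = centers.copy()
        for j in range(k):
            sel = new_assignment == j
            wj = weights[sel]
            if wj.sum() > 0:
                new_centers[j] = (coords[sel] * wj[:, None]).sum(axis=0) / wj.sum()
        if assignment is not None and np.array_equal(new_assignment, assignment) and np.allclose(
            new_centers, centers, atol=1e-12
        ):
            converged = True
            centers = new_centers
            assignment = new_assignment
            break
        centers, assignment = new_centers, new_assignment
    if not converged and max_iter > 1:
        warnings.warn("weighted k-means hit max_iter; returning best iterate", NonConvergenceWarning)

    detections = []
    for j in range(k):
        sel = assignment == j
        wj = float(weights[sel].sum())
        detections.append(AnkleDetection(centers[j], wj, int(sel.sum())))
    detections.sort(key=lambda det: (-det.total_weight, det.center_mm[0]))

    if k == 2:
        gap = float(np.linalg.norm(detections[0].center_mm - detections[1].center_mm))
        if gap < merge_distance_mm:
            warnings.warn(
                f"k=2 centers only {gap:.1f} mm apart; merging into one detection",
                DuplicateDetectionWarning,
            )
            w0, w1 = detections[0].total_weight, detections[1].total_weight
            merged_center = (detections[0].center_mm * w0 + detections[1].center_mm * w1) / (w0 + w1)
            detections = [
                AnkleDetection(
                    merged_center,
                    w0 + w1,
                    detections[0].member_voxel_count + detections[1].member_voxel_count,
                    merged=True,
                )
            ]
    return detections


def localize(
    volume: ScalarVolume,
    predictor: Callable[[ScalarVolume], np.ndarray],
    n_ankles: int,
    *,
    patch_size: int = 64,
    stride: int = 32,
    seed: int = 0,
    weight_floor: float = 0.05,
    merge_distance_mm: float = 40.0,
) -> list[AnkleDetection]:
    """Full stage 1: sliding-window prediction, fusion, weighted clustering.

    ``predictor`` maps a patch :class:`ScalarVolume` to a same-shaped array
    of foreground probabilities; it is either the trained localizer U-Net
    or the ground-truth oracle.  ``n_ankles`` (1 or 2) is declared by the
    caller, mirroring the tool's single- and double-ankle modes.
    """
    patches = extract_patches(volume, patch_size, stride)
    preds = [(np.asarray(predictor(p), dtype=np.float64), off) for p, off in patches]
    fused = fuse_predictions(preds, volume.grid)
    return weighted_kmeans(
        fused,
        k=n_ankles,
        seed=seed,
        weight_floor=weight_floor,
        merge_distance_mm=merge_distance_mm,
    )
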