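"""Oracle segmenters: ground-truth masks standing in for trained weights.

The oracles answer segmentation queries from the phantom's exact ground
truth, optionally corrupted with seeded label-flip noise (a fraction of
labeled voxels switched off and an equal count of background voxels near
the structure switched on).  They exercise the full geometric pipeline
independently of training quality and give a controlled noise dial for
robustness experiments.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..geometry import ScalarVolume, world_to_voxel
from ..masks import CylinderMaskSpec, PlaneLabelVolume, SphereMaskSpec, make_plane_cylinder_masks, make_sphere_mask
from ..phantom import PhantomSample

__all__ = ["oracle_sphere_predictor", "oracle_plane_segmenter", "apply_label_noise"]

_OFFSET_BIAS = 10**6  # makes crop offsets non-negative for rng seeding


def apply_label_noise(labels: np.ndarray, noise_rate: float, rng: np.random.Generator, near_voxels: int = 3) -> np.ndarray:
    """Flip ``round(noise_rate·n_fg)`` labeled voxels to background and turn on
    the same count of background voxels within ``near_voxels`` of the structure.

    Switched-on voxels receive a random foreground class drawn from the
    classes present.  ``noise_rate`` must lie in [0, 0.5).
    """
    if not 0 <= noise_rate < 0.5:
        raise ValueError("noise_rate must be in [0, 0.5)")
    labels = np.asarray(labels)
    if noise_rate == 0:
        return labels.copy()
    out = labels.copy()
    fg_idx = np.argwhere(labels > 0)
    n_flip = int(round(noise_rate * fg_idx.shape[0]))
    if n_flip == 0:
        return out
    classes = np.unique(labels[labels > 0])
    off = fg_idx[rng.choice(fg_idx.shape[0], size=n_flip, replace=False)]
    near = ndimage.binary_dilation(labels > 0, iterations=near_voxels) & (labels == 0)
    bg_idx = np.argwhere(near)
    n_on = min(n_flip, bg_idx.shape[0])
    on = bg_idx[rng.choice(bg_idx.shape[0], size=n_on, replace=False)]
    out[tuple(off.T)] = 0
    out[tuple(on.T)] = rng.choice(classes, size=n_on)
    return out


def _region_rng(seed: int, origin_voxel: np.ndarray) -> np.random.Generator:
    key = [int(seed)] + [int(v) + _OFFSET_BIAS for v in origin_voxel]
    return np.random.default_rng(key)


def oracle_sphere_predictor(sample: PhantomSample, noise_rate: float = 0.0, seed: int = 0, radius_mm: float = 5.0):
    """Patch predictor returning the (noised) ground-truth sphere probability.

    The noisy full-volume mask is drawn once, so every patch sees a
    consistent segmentation regardless of the sliding-window layout.
    """
    grid = sample.volume.grid
    full = np.zeros(grid.shape, dtype=np.uint8)
    for frame in sample.frames:
        full = np.maximum(
            full, make_sphere_mask(SphereMaskSpec(tuple(frame.intersection_mm), radius_mm), grid)
        )
    full = apply_label_noise(full, noise_rate, np.random.default_rng(seed))

    def predictor(patch: ScalarVolume) -> np.ndarray:
        off = np.round(world_to_voxel(patch.grid.origin_mm, grid)).astype(int)
        sl = tuple(slice(o, o + s) for o, s in zip(off, patch.grid.shape))
        return full[sl].astype(np.float64)

    return predictor


def oracle_plane_segmenter(
    sample: PhantomSample,
    noise_rate: float = 0.0,
    seed: int = 0,
    radius_mm: float | None = None,
    height_mm: float | None = None,
):
    """ROI segmenter voxelizing the nearest ground-truth frame's cylinders.

    Masks are rendered directly on the ROI grid (so crop-boundary clipping
    behaves exactly like a segmentation of the cropped image) and noised
    with an rng keyed on the seed and the ROI origin, which keeps repeated
    calls reproducible.
    """
    spec = sample.spec
    radius_mm = radius_mm if radius_mm is not None else (spec.mask_radius_mm if spec else 25.0)
    height_mm = height_mm if height_mm is not None else (spec.mask_height_mm if spec else 2.0)

    def segmenter(roi: ScalarVolume) -> PlaneLabelVolume:
        center = roi.grid.center_mm
        dists = [np.linalg.norm(f.intersection_mm - center) for f in sample.frames]
        frame = sample.frames[int(np.argmin(dists))]
        label_volume = make_plane_cylinder_masks(CylinderMaskSpec(frame, radius_mm, height_mm), roi.grid)
        origin_voxel = np.round(world_to_voxel(roi.grid.origin_mm, sample.volume.grid)).astype(int)
        noisy = apply_label_noise(label_volume.labels, noise_rate, _region_rng(seed, origin_voxel))
        return PlaneLabelVolume(roi.grid, noisy)

    return segmenter
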