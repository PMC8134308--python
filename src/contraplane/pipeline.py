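"""End-to-end pipeline: localize → crop → estimate planes → align/compare."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .alignment import ComparisonView, LEVEL_OFFSETS_MM, build_comparison, orient_frame_to_anatomy
from .config import PipelineConfig
from .errors import PipelineStageError
from .geometry import ScalarVolume, StandardPlaneFrame
from .localization import AnkleDetection, localize
from .planes import PlaneEstimate, crop_roi, estimate_planes

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    detections: list[AnkleDetection]
    estimates: list[PlaneEstimate]
    frames: list[StandardPlaneFrame]
    views: dict[str, ComparisonView] = field(default_factory=dict)


def run_pipeline(
    volume: ScalarVolume,
    localizer: Callable,
    plane_segmenter: Callable,
    n_ankles: int,
    config: PipelineConfig | None = None,
    crop_size: int | None = None,
) -> PipelineResult:
    """Run both stages and, for bilateral input, build the three view pairs.

    ``localizer`` maps a patch volume to foreground probabilities;
    ``plane_segmenter`` maps an ROI volume to a 4-class label volume.  Each
    estimated frame is sign-anchored to the image content so its handedness
    tags the anatomical laterality.  Errors carry the failing stage's tag.
    """
    config = config or PipelineConfig()
    loc_cfg = config.localization
    if crop_size is None:
        crop_size = (
            config.planes.crop_size_bilateral if n_ankles == 2 else config.planes.crop_size_unilateral
        )
    try:
        detections = localize(
            volume,
            localizer,
            n_ankles,
            patch_size=loc_cfg.patch_size,
            stride=loc_cfg.stride,
            seed=config.seed,
            weight_floor=loc_cfg.weight_floor,
            merge_distance_mm=loc_cfg.merge_distance_mm,
        )
    except Exception as exc:  # noqa: BLE001 - re-raise with stage tag
        raise PipelineStageError("localization", exc) from exc

    estimates: list[PlaneEstimate] = []
    frames: list[StandardPlaneFrame] = []
    for det in detections:
        try:
            roi = crop_roi(volume, det.center_mm, crop_size)
            est = estimate_planes(
                roi,
                plane_segmenter,
                min_voxels=config.planes.min_voxels,
                intersection_mode=config.planes.intersection_mode,
            )
            oriented = orient_frame_to_anatomy(est.frame, roi.volume)
            est.frame = oriented
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("plane_estimation", exc) from exc
        estimates.append(est)
        frames.append(est.frame)

    views: dict[str, ComparisonView] = {}
    if len(frames) == 2:
        try:
            for level in LEVEL_OFFSETS_MM:
                views[level] = build_comparison(
                    volume,
                    tuple(frames),
                    level=level,
                    extent_mm=config.view.extent_mm,
                    pixel_mm=config.view.pixel_mm,
                )
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("alignment_view", exc) from exc
    return PipelineResult(detections, estimates, frames, views)
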