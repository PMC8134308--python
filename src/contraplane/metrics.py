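"""Evaluation metrics (pos, pos2Ax, per-plane angles) and summary harness.

``pos`` is the 3D Euclidean distance between predicted and true
intersection points; ``pos2Ax`` is the shortest distance from the
predicted intersection to the *true* axial plane — the clinically dominant
error, since it shifts the level at which the reduction is inspected.
Angular errors are measured per plane normal, folded to [0°, 90°] via the
absolute dot product because normal signs are convention-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import StandardPlaneFrame
from .phantom import PhantomSample

__all__ = ["FrameErrors", "SummaryStats", "frame_errors", "summarize", "evaluate_run"]

METRIC_NAMES = ("pos_mm", "pos2ax_mm", "ang_sag_deg", "ang_ax_deg", "ang_cor_deg")


@dataclass
class FrameErrors:
    """Per-case deviation between a predicted and a ground-truth frame."""

    pos_mm: float
    pos2ax_mm: float
    ang_sag_deg: float
    ang_ax_deg: float
    ang_cor_deg: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class SummaryStats:
    """Median / sd / max per metric; sd both over cases and over group medians."""

    median: dict[str, float]
    sd: dict[str, float]
    sd_over_group_medians: dict[str, float]
    max: dict[str, float]
    n_cases: int
    n_groups: int
    single_group_sd_flag: bool = False


def _angle_deg(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.degrees(np.arccos(np.clip(abs(float(a @ b)), 0.0, 1.0))))


def frame_errors(predicted: StandardPlaneFrame, truth: StandardPlaneFrame) -> FrameErrors:
    """pos, pos-to-axial-plane and the three sign-invariant normal angles.

    ``pos2ax`` projects the intersection offset onto the *true* axial
    normal, so it is bounded above by ``pos``.
    """
    delta = predicted.intersection_mm - truth.intersection_mm
    pos = float(np.linalg.norm(delta))
    pos2ax = abs(float(delta @ truth.n_ax))
    return FrameErrors(
        pos,
        pos2ax,
        _angle_deg(predicted.n_sag, truth.n_sag),
        _angle_deg(predicted.n_ax, truth.n_ax),
        _angle_deg(predicted.n_cor, truth.n_cor),
    )


def summarize(errors: Sequence[FrameErrors], groups: Sequence | None = None) -> SummaryStats:
    """Median, sd and max per metric, plus the sd over per-group medians.

    The per-group variant mirrors fold-wise reporting: the sd is computed
    over the medians of each group (fold/dataset).  With a single group (or
    no grouping) that sd is reported as 0 with a flag.
    """
    if len(errors) == 0:
        raise ValueError("summarize: empty error list")
    if groups is None:
        groups = [0] * len(errors)
    if len(groups) != len(errors):
        raise ValueError("groups must match errors in length")
    values = {name: np.array([getattr(e, name) for e in errors], dtype=float) for name in METRIC_NAMES}
    unique_groups = sorted(set(groups), key=lambda g: str(g))
    median = {k: float(np.median(v)) for k, v in values.items()}
    sd = {k: float(np.std(v, ddof=0)) for k, v in values.items()}
    maxima = {k: float(np.max(v)) for k, v in values.items()}
    flag = len(unique_groups) < 2
    if flag:
        sd_groups = {k: 0.0 for k in values}
    else:
        garr = np.asarray(groups)
        sd_groups = {}
        for k, v in values.items():
            group_medians = [float(np.median(v[garr == g])) for g in unique_groups]
            sd_groups[k] = float(np.std(np.asarray(group_medians), ddof=0))
    return SummaryStats(median, sd, sd_groups, maxima, len(errors), len(unique_groups), flag)


@dataclass
class EvaluationReport:
    stats: SummaryStats
    per_case: list[dict]
    n_unmatched: int = 0


def _match_predictions(pred_frames, truth_frames):
    """Pair predictions with truths by nearest intersection (Hungarian)."""
    cost = np.array(
        [
            [np.linalg.norm(p.intersection_mm - t.intersection_mm) for t in truth_frames]
            for p in pred_frames
        ]
    )
    rows, cols = linear_sum_assignment(cost)
    return list(zip(rows.tolist(), cols.tolist()))


def evaluate_run(
    samples: Sequence[PhantomSample],
    pipeline: Callable[[PhantomSample], list[StandardPlaneFrame]],
    groups: Sequence | None = None,
) -> EvaluationReport:
    """Run a pipeline over phantoms and summarize frame errors.

    ``pipeline`` maps a sample to its predicted frames (any count).
    Predictions are matched to ground-truth frames by nearest intersection
    point; truths left unmatched (or surplus predictions) are counted and
    reported, never silently dropped.
    """
    if len(samples) == 0:
        raise ValueError("evaluate_run: empty sample list")
    if groups is None:
        groups = [0] * len(samples)
    errors: list[FrameErrors] = []
    error_groups: list = []
    rows: list[dict] = []
    n_unmatched = 0
    for sample_idx, (sample, group) in enumerate(zip(samples, groups)):
        predicted = pipeline(sample)
        pairs = _match_predictions(predicted, sample.frames) if predicted else []
        matched_truths = {j for _, j in pairs}
        n_unmatched += (len(sample.frames) - len(matched_truths)) + (len(predicted) - len(pairs))
        for i, j in pairs:
            err = frame_errors(predicted[i], sample.frames[j])
            errors.append(err)
            error_groups.append(group)
            rows.append(
                {
                    "sample": sample_idx,
                    "ankle": j,
                    "laterality_truth": sample.lateralities[j],
                    "laterality_pred": predicted[i].handedness,
                    **err.as_dict(),
                }
            )
    if not errors:
        raise ValueError("evaluate_run: no prediction could be matched to a ground truth")
    return EvaluationReport(summarize(errors, error_groups), rows, n_unmatched)
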