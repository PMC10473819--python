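"""Segmentation evaluation: Dice scores, failure detection, difficulty AUC.

Failure here means an anatomically infeasible myocardium mask: the foreground
is empty or splits into more than one 8-connected component (a broken ring).
The difficulty analysis asks whether the per-frame uncertainty ``q_frame``
ranks hard-to-delineate frames above easy ones, slice by slice: each dynamic
series yields its own threshold classifier (heart size, and hence the dQC
scale, varies across series), and the dataset summary is the mean +/- std of
the per-slice ROC AUCs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage.measure import label as _cc_label
from sklearn.metrics import roc_auc_score

from .metrics import FrameMetrics
from .patch_ops import MaskSeries

__all__ = [
    "DiceReport",
    "FailureReport",
    "AucReport",
    "dice",
    "dice_2d",
    "dice_3d",
    "is_contiguous",
    "failure_prevalence",
    "difficulty_auc",
]

logger = logging.getLogger("dynqc")


@dataclass(eq=False)
class DiceReport:
    """Per-frame (2D) and pooled (2D+time) Dice overlap of two mask series."""

    dice_2d: np.ndarray
    dice_3d: float

    @property
    def mean_2d(self) -> float:
        return float(np.mean(self.dice_2d))

    @property
    def std_2d(self) -> float:
        return float(np.std(self.dice_2d))


@dataclass(eq=False)
class FailureReport:
    """Non-contiguity failures over a collection of mask series.

    ``failed`` concatenates per-frame flags in input order; ``prevalence`` is
    their mean.
    """

    failed: np.ndarray
    prevalence: float


@dataclass(eq=False)
class AucReport:
    """Per-slice difficulty-classification AUCs and their summary.

    ``per_slice`` holds NaN for slices excluded because all their frames share
    one grade.
    """

    per_slice: np.ndarray
    mean: float
    std: float
    n_included: int


def _check_pair(a: MaskSeries, b: MaskSeries) -> None:
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")


def dice_2d(a: MaskSeries, b: MaskSeries) -> np.ndarray:
    """Per-frame Dice 2|A∩B|/(|A|+|B|); both-empty frames score 1."""
    _check_pair(a, b)
    inter = (a.data & b.data).sum(axis=(0, 1)).astype(np.float64)
    tot = a.data.sum(axis=(0, 1)) + b.data.sum(axis=(0, 1))
    out = np.ones(a.shape[2], dtype=np.float64)
    nz = tot > 0
    out[nz] = 2.0 * inter[nz] / tot[nz]
    return out


def dice_3d(a: MaskSeries, b: MaskSeries) -> float:
    """Spatiotemporal (2D+time) Dice pooled over all M*N*T voxels."""
    _check_pair(a, b)
    inter = int((a.data & b.data).sum())
    tot = int(a.data.sum()) + int(b.data.sum())
    return 1.0 if tot == 0 else 2.0 * inter / tot


def dice(a: MaskSeries, b: MaskSeries, mode: str = "3d") -> DiceReport:
    """Dice report for two mask series (both per-frame and pooled values).

    ``mode`` selects which number is the headline (``"2d"`` or ``"3d"``); both
    are always computed and reported.
    """
    if mode not in ("2d", "3d"):
        raise ValueError(f"mode must be '2d' or '3d', got {mode!r}")
    return DiceReport(dice_2d=dice_2d(a, b), dice_3d=dice_3d(a, b))


def is_contiguous(frame_mask: np.ndarray) -> bool:
    """True iff the foreground is exactly one 8-connected component.

    Empty masks are *not* contiguous: an absent myocardium counts as a failed
    segmentation.  8-connectivity keeps a one-pixel-wide diagonal ring segment
    intact.
    """
    frame_mask = np.asarray(frame_mask)
    if frame_mask.ndim != 2:
        raise ValueError("is_contiguous expects a single 2-D frame")
    if not frame_mask.any():
        return False
    _, n = _cc_label(frame_mask > 0, connectivity=2, return_num=True)
    return n == 1


def failure_prevalence(masks: Sequence[MaskSeries]) -> FailureReport:
    """Fraction of all frames (pooled over the collection) that fail contiguity."""
    if len(masks) == 0:
        raise ValueError("failure_prevalence needs at least one mask series")
    flags = []
    for m in masks:
        for t in range(m.shape[2]):
            flags.append(not is_contiguous(m.frame(t)))
    failed = np.asarray(flags, dtype=bool)
    return FailureReport(failed=failed, prevalence=float(failed.mean()))


def difficulty_auc(
    fms: Sequence[FrameMetrics], labels: Sequence[np.ndarray]
) -> AucReport:
    """Per-slice ROC AUC of ``q_frame`` against binary difficulty grades.

    Each slice gets its own classifier: its frames are ranked by that slice's
    ``q_frame`` values and swept against the grade labels (1 = high-grade
    difficulty).  Ties contribute 0.5 per tied pair (Mann–Whitney convention).
    Slices whose frames all share one grade carry no ranking information and
    are excluded with a logged warning.
    """
    if len(fms) != len(labels):
        raise ValueError("need one label vector per slice")
    per_slice = np.full(len(fms), np.nan)
    for i, (fm, grade) in enumerate(zip(fms, labels)):
        grade = np.asarray(grade, dtype=int)
        if grade.shape != fm.q_frame.shape:
            raise ValueError(f"slice {i}: labels length {grade.shape} != T {fm.q_frame.shape}")
        if not np.isin(grade, (0, 1)).all():
            raise ValueError(f"slice {i}: grades must be binary")
        if grade.min() == grade.max():
            logger.warning(
                "slice %d has a single difficulty class; excluded from AUC summary", i
            )
            continue
        per_slice[i] = roc_auc_score(grade, fm.q_frame)
    included = per_slice[~np.isnan(per_slice)]
    if included.size == 0:
        return AucReport(per_slice=per_slice, mean=float("nan"), std=float("nan"), n_included=0)
    return AucReport(
        per_slice=per_slice,
        mean=float(included.mean()),
        std=float(included.std()),
        n_included=int(included.size),
    )
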