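"""Uncertainty metrics derived from the dQC map.

Three levels of granularity, all normalized by the predicted segmentation
area of the frame so that uncertainty is judged relative to the size of the
segmented structure:

* ``q_pixel``: the dQC value at each space-time location divided by the
  frame's segmentation area (pixels);
* ``q_frame``: the Frobenius norm of the dQC map's frame divided by that
  frame's segmentation area — the per-frame uncertainty used to rank frames
  for referral;
* ``q_slice``: the time-average of ``q_frame`` — the overall quality score of
  one dynamic series.

Frames with an empty predicted mask have an undefined normalization; they use
divisor ``max(area, 1)`` and carry a ``degenerate`` flag.  An empty myocardium
is anatomically infeasible, so referral ranking forces flagged frames to the
front — the flag never hides a catastrophic failure behind a finite score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .patch_ops import MaskSeries

__all__ = ["FrameMetrics", "q_pixel", "q_frame", "q_slice", "frame_metrics_table"]


@dataclass(eq=False)
class FrameMetrics:
    """Per-frame uncertainty of one dynamic series.

    Attributes
    ----------
    q_frame
        Nonnegative per-frame uncertainty, length ``T``.
    seg_area
        Predicted segmentation area per frame (pixels).
    degenerate
        True where the predicted mask is empty (score computed with divisor 1).
    """

    q_frame: np.ndarray
    seg_area: np.ndarray
    degenerate: np.ndarray

    def __post_init__(self) -> None:
        self.q_frame = np.asarray(self.q_frame, dtype=np.float64)
        self.seg_area = np.asarray(self.seg_area, dtype=np.int64)
        self.degenerate = np.asarray(self.degenerate, dtype=bool)
        if not (self.q_frame.shape == self.seg_area.shape == self.degenerate.shape):
            raise ValueError("q_frame, seg_area and degenerate must share length")
        if np.any(self.q_frame < 0) or not np.all(np.isfinite(self.q_frame)):
            raise ValueError("q_frame must be finite and nonnegative")

    @property
    def T(self) -> int:
        return self.q_frame.shape[0]


def _check_shapes(dqc_map: np.ndarray, mask: MaskSeries) -> np.ndarray:
    dqc_map = np.asarray(dqc_map, dtype=np.float64)
    if dqc_map.shape != mask.shape:
        raise ValueError(
            f"dQC map shape {dqc_map.shape} != mask shape {mask.shape}"
        )
    return dqc_map


def q_pixel(dqc_map: np.ndarray, mask: MaskSeries) -> np.ndarray:
    """Pixel-level uncertainty: dQC value / frame segmentation area.

    Returns an ``(M, N, T)`` array; frames with empty masks use divisor 1.
    """
    dqc_map = _check_shapes(dqc_map, mask)
    area = mask.data.sum(axis=(0, 1)).astype(np.float64)
    return dqc_map / np.maximum(area, 1.0)[None, None, :]


def q_frame(dqc_map: np.ndarray, mask: MaskSeries) -> FrameMetrics:
    """Frame-level uncertainty: ||dQC frame||_F / frame segmentation area."""
    dqc_map = _check_shapes(dqc_map, mask)
    area = mask.data.sum(axis=(0, 1)).astype(np.int64)
    fro = np.sqrt(np.sum(dqc_map * dqc_map, axis=(0, 1)))
    q = fro / np.maximum(area, 1).astype(np.float64)
    return FrameMetrics(q_frame=q, seg_area=area, degenerate=(area == 0))


def q_slice(fm: FrameMetrics) -> float:
    """Series-level uncertainty: arithmetic mean of ``q_frame`` over all frames.

    Degenerate frames contribute their flagged (divisor-1) values.
    """
    return float(np.mean(fm.q_frame))


def frame_metrics_table(fm: FrameMetrics) -> pd.DataFrame:
    """Tabulate per-frame metrics with 1-based frame indices for export."""
    return pd.DataFrame(
        {
            "frame_index": np.arange(1, fm.T + 1),
            "q_frame": fm.q_frame,
            "seg_area": fm.seg_area,
            "degenerate": fm.degenerate,
        }
    )
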