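"""Human-in-the-loop referral simulation under a fixed correction budget.

Scenario: a fixed fraction of all time frames (10% by default) can be sent to
a human expert for correction.  Two selection arms are compared against the
uncorrected baseline:

* **dQC arm** — frames ranked by per-frame uncertainty ``q_frame`` pooled
  globally across slices (degenerate frames — empty predicted masks — forced
  to the front); deterministic.
* **random arm** — a uniform sample of the same size, repeated over Monte
  Carlo runs.

The simulated expert either replaces every referred frame with ground truth
(``oracle``) or, like a real reader, corrects only the frames it judges
erroneous (``reluctant``): non-contiguous or empty masks, masks leaking into
the blood pool, or masks with 2D Dice below a threshold.  Post-correction
scores are cumulative — recomputed over ALL frames, corrected or not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Hashable, List, Sequence, Tuple

import numpy as np

from .evaluation import dice_2d, dice_3d, failure_prevalence, is_contiguous
from .metrics import FrameMetrics, q_frame
from .patch_ops import MaskSeries, Segmenter, compute_dqc_map, segment_series

__all__ = [
    "ReferralPlan",
    "ExpertPolicy",
    "HitlConfig",
    "ArmResult",
    "HitlReport",
    "select_topk",
    "select_random",
    "apply_expert",
    "run_experiment",
]

logger = logging.getLogger("dynqc")

FrameKey = Tuple[Hashable, int]  # (slice_id, 0-based frame index)


def _budget(fraction: float, total: int) -> int:
    # round-half-up on fraction * total
    return int(np.floor(fraction * total + 0.5))


@dataclass(eq=False)
class ReferralPlan:
    """The set of (slice_id, frame) pairs selected for expert referral."""

    selected: Tuple[FrameKey, ...]
    budget_fraction: float
    method: str  # "dqc" | "random"

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("referral plan contains duplicate frames")

    def frames_for(self, slice_id: Hashable) -> List[int]:
        return sorted(t for s, t in self.selected if s == slice_id)


@dataclass(frozen=True)
class ExpertPolicy:
    """Simulated expert behavior.

    ``oracle`` replaces every referred frame with ground truth.  ``reluctant``
    replaces a referred frame only when it judges it erroneous: non-contiguous
    or empty foreground, overlap with the blood pool exceeding
    ``bp_overlap_threshold`` of the predicted area, or 2D Dice below
    ``dice_threshold``.
    """

    kind: str = "reluctant"
    dice_threshold: float = 0.6
    bp_overlap_threshold: float = 0.1

    def __post_init__(self) -> None:
        if self.kind not in ("oracle", "reluctant"):
            raise ValueError(f"unknown expert policy {self.kind!r}")


def select_topk(
    metrics: Dict[Hashable, FrameMetrics], fraction: float
) -> ReferralPlan:
    """Select the top-``fraction`` most uncertain frames, pooled globally.

    Frames are ranked by ``q_frame`` across all slices; degenerate-flagged
    frames (empty predictions, anatomically infeasible) are forced to the
    front regardless of score; ties break by (slice_id, frame) ascending.
    """
    if not metrics:
        raise ValueError("empty dataset")
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rows: List[Tuple[int, float, Hashable, int]] = []
    for sid, fm in metrics.items():
        for t in range(fm.T):
            rows.append((0 if fm.degenerate[t] else 1, -float(fm.q_frame[t]), sid, t))
    rows.sort()
    n_sel = _budget(fraction, len(rows))
    selected = tuple((sid, t) for _, _, sid, t in rows[:n_sel])
    return ReferralPlan(selected=selected, budget_fraction=fraction, method="dqc")


def select_random(
    frames: Sequence[FrameKey], fraction: float, seed: int
) -> ReferralPlan:
    """Uniform sample (without replacement) of the same budget, seeded."""
    if len(frames) == 0:
        raise ValueError("empty dataset")
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    frames = sorted(frames)
    n_sel = _budget(fraction, len(frames))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(frames), size=n_sel, replace=False)
    selected = tuple(frames[i] for i in sorted(idx))
    return ReferralPlan(selected=selected, budget_fraction=fraction, method="random")


def _needs_correction(
    pred_frame: np.ndarray,
    gt_frame: np.ndarray,
    d2d: float,
    policy: ExpertPolicy,
    bp_frame: np.ndarray | None,
) -> bool:
    if policy.kind == "oracle":
        return True
    area = int(pred_frame.sum())
    if area == 0 or not is_contiguous(pred_frame):
        return True
    if bp_frame is not None:
        leak = int((pred_frame.astype(bool) & bp_frame.astype(bool)).sum())
        if leak / area > policy.bp_overlap_threshold:
            return True
    return d2d < policy.dice_threshold


def apply_expert(
    pred: MaskSeries,
    gt: MaskSeries,
    frames: Sequence[int],
    policy: ExpertPolicy,
    blood_pool: MaskSeries | None = None,
) -> Tuple[MaskSeries, int]:
    """Apply the expert policy to the referred frames of one slice.

    Returns the corrected mask series (role ``corrected``) and the number of
    referred frames the expert actually changed (a referred frame it judged
    acceptable — or one already identical to ground truth — does not count).
    Frames outside ``frames`` are untouched.
    """
    if gt is None:
        raise ValueError("expert correction requires ground truth")
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground truth shapes differ")
    out = pred.data.copy()
    d2d = dice_2d(pred, gt)
    n_corrected = 0
    for t in frames:
        pf = pred.data[:, :, t]
        gf = gt.data[:, :, t]
        bp = blood_pool.data[:, :, t] if blood_pool is not None else None
        if _needs_correction(pf, gf, float(d2d[t]), policy, bp):
            if not np.array_equal(pf, gf):
                out[:, :, t] = gf
                n_corrected += 1
    return MaskSeries(out, role="corrected"), n_corrected


@dataclass(frozen=True)
class HitlConfig:
    """Geometry and referral settings of one experiment.

    ``K``/``w_S``/``w_M``: patch size and segmentation/dQC strides;
    ``fraction``: referral budget as a fraction of all frames; ``n_mc``:
    Monte Carlo repeats of the random arm; ``per_slice``: rank the budget
    within each slice instead of pooling globally.
    """

    K: int = 64
    w_S: int = 16
    w_M: int = 2
    fraction: float = 0.1
    policy: ExpertPolicy = field(default_factory=ExpertPolicy)
    n_mc: int = 100
    seed: int = 0
    per_slice: bool = False


@dataclass(eq=False)
class ArmResult:
    """Cumulative (all-frames) outcome of one referral arm."""

    dice_3d_mean: float
    dice_3d_std: float
    prevalence: float
    corrected_fraction: float
    selected_initial_dice_2d: float

    def as_dict(self) -> dict:
        return {
            "dice_3d_mean": self.dice_3d_mean,
            "dice_3d_std": self.dice_3d_std,
            "prevalence": self.prevalence,
            "corrected_fraction": self.corrected_fraction,
            "selected_initial_dice_2d": self.selected_initial_dice_2d,
        }


@dataclass(eq=False)
class HitlReport:
    """Baseline vs random vs dQC-guided referral, cumulative over all frames.

    The random arm is the average over ``n_mc`` Monte Carlo runs (per-run
    values in ``random_runs``); the baseline and dQC arms are deterministic.
    """

    baseline: ArmResult
    random: ArmResult
    dqc: ArmResult
    random_runs: List[ArmResult]
    n_slices: int
    n_frames: int
    budget: int
    config: HitlConfig
    frame_metrics: Dict[Hashable, FrameMetrics] = field(default_factory=dict)
    baseline_dice_2d: Dict[Hashable, np.ndarray] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_slices": self.n_slices,
            "n_frames": self.n_frames,
            "budget": self.budget,
            "baseline": self.baseline.as_dict(),
            "random": self.random.as_dict(),
            "dqc": self.dqc.as_dict(),
        }


def _plan_per_slice(metrics: Dict[Hashable, FrameMetrics], fraction: float) -> ReferralPlan:
    parts: List[FrameKey] = []
    for sid, fm in metrics.items():
        sub = select_topk({sid: fm}, fraction)
        parts.extend(sub.selected)
    return ReferralPlan(selected=tuple(parts), budget_fraction=fraction, method="dqc")


def _evaluate_arm(
    preds: Dict[Hashable, MaskSeries],
    gts: Dict[Hashable, MaskSeries],
    baseline_d2d: Dict[Hashable, np.ndarray],
    plan: ReferralPlan | None,
    policy: ExpertPolicy,
    blood_pools: Dict[Hashable, MaskSeries | None],
) -> ArmResult:
    corrected: Dict[Hashable, MaskSeries] = {}
    n_referred = 0
    n_changed = 0
    sel_d2d: List[float] = []
    for sid, pred in preds.items():
        frames = plan.frames_for(sid) if plan is not None else []
        n_referred += len(frames)
        sel_d2d.extend(float(baseline_d2d[sid][t]) for t in frames)
        fixed, n_c = apply_expert(pred, gts[sid], frames, policy, blood_pools[sid])
        n_changed += n_c
        corrected[sid] = fixed
    per_slice_dice = np.array([dice_3d(corrected[s], gts[s]) for s in preds])
    prev = failure_prevalence(list(corrected.values())).prevalence
    return ArmResult(
        dice_3d_mean=float(per_slice_dice.mean()),
        dice_3d_std=float(per_slice_dice.std()),
        prevalence=prev,
        corrected_fraction=(n_changed / n_referred) if n_referred else 0.0,
        selected_initial_dice_2d=float(np.mean(sel_d2d)) if sel_d2d else float("nan"),
    )


def run_experiment(
    dataset: Sequence,
    make_segmenter,
    config: HitlConfig,
) -> HitlReport:
    """Run the full referral experiment on a dataset of dynamic slices.

    Parameters
    ----------
    dataset
        Sequence of slice bundles; each item must expose ``series``, ``gt``
        and (optionally) ``blood_pool`` attributes (a phantom bundle fits).
    make_segmenter
        Callable ``bundle -> Segmenter`` giving each slice its segmenter.
    config
        Geometry, budget, policy, Monte Carlo settings.

    The baseline segmentation, dQC map and frame metrics are computed once per
    slice; the dQC arm runs once (it is deterministic), the random arm
    ``config.n_mc`` times with per-run seeds derived from ``config.seed``.
    A budget fraction of 0 short-circuits selection: all arms equal baseline.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if not (0.0 <= config.fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")

    preds: Dict[Hashable, MaskSeries] = {}
    gts: Dict[Hashable, MaskSeries] = {}
    bps: Dict[Hashable, MaskSeries | None] = {}
    fms: Dict[Hashable, FrameMetrics] = {}
    d2d: Dict[Hashable, np.ndarray] = {}
    all_frames: List[FrameKey] = []
    for sid, bundle in enumerate(dataset):
        seg = make_segmenter(bundle)
        pred = segment_series(bundle.series, seg, config.K, config.w_S)
        dqc = compute_dqc_map(bundle.series, seg, config.K, config.w_M, w_S=config.w_S)
        preds[sid] = pred
        gts[sid] = bundle.gt
        bps[sid] = getattr(bundle, "blood_pool", None)
        fms[sid] = q_frame(dqc, pred)
        d2d[sid] = dice_2d(pred, bundle.gt)
        all_frames.extend((sid, t) for t in range(bundle.series.shape[2]))
        logger.info("slice %s: segmented, q_slice=%.4g", sid, float(fms[sid].q_frame.mean()))

    baseline = _evaluate_arm(preds, gts, d2d, None, config.policy, bps)
    n_frames = len(all_frames)

    if config.fraction == 0.0:
        logger.info("budget fraction 0: all arms identical to baseline")
        return HitlReport(
            baseline=baseline,
            random=baseline,
            dqc=baseline,
            random_runs=[baseline] * config.n_mc,
            n_slices=len(dataset),
            n_frames=n_frames,
            budget=0,
            config=config,
            frame_metrics=fms,
            baseline_dice_2d=d2d,
        )

    if config.per_slice:
        dqc_plan = _plan_per_slice(fms, config.fraction)
    else:
        dqc_plan = select_topk(fms, config.fraction)
    dqc_arm = _evaluate_arm(preds, gts, d2d, dqc_plan, config.policy, bps)

    runs: List[ArmResult] = []
    for run in range(config.n_mc):
        plan = select_random(all_frames, config.fraction, seed=config.seed * 10007 + run)
        runs.append(_evaluate_arm(preds, gts, d2d, plan, config.policy, bps))
    random_arm = ArmResult(
        dice_3d_mean=float(np.mean([r.dice_3d_mean for r in runs])),
        dice_3d_std=float(np.mean([r.dice_3d_std for r in runs])),
        prevalence=float(np.mean([r.prevalence for r in runs])),
        corrected_fraction=float(np.mean([r.corrected_fraction for r in runs])),
        selected_initial_dice_2d=float(np.mean([r.selected_initial_dice_2d for r in runs])),
    )
    return HitlReport(
        baseline=baseline,
        random=random_arm,
        dqc=dqc_arm,
        random_runs=runs,
        n_slices=len(dataset),
        n_frames=n_frames,
        budget=len(dqc_plan.selected),
        config=config,
        frame_metrics=fms,
        baseline_dice_2d=d2d,
    )
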