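"""Synthetic dynamic contrast-enhanced phantom and simulated segmenter.

The phantom emulates one short-axis perfusion slice: a ring-shaped myocardium
around a circular left-ventricular blood pool, imaged over ``T`` frames while
a contrast bolus washes in and out.  Intensities follow gamma-variate
enhancement curves — the blood pool enhances early and strongly, the
myocardium later and more weakly — on a constant tissue background.  The ring
center drifts with a breathing-like sinusoid plus seeded jitter, the frame is
smoothed by a small point-spread blur, and Gaussian noise is added.  Ground
truth (the crisp ring per frame) and the blood-pool mask are returned next to
the images.

Frame difficulty is graded by rule from the noise-free enhancement curves:
a frame is *grade 1* (high difficulty) when BOTH the endocardial contrast
``|myo - blood|`` and the epicardial contrast ``|myo - background|`` are
weak, i.e. when the larger of the two, ``max(|myo - blood|,
|myo - background|)``, falls below a threshold.  With the default curves this
flags the pre-contrast frames and the fully-washed-out tail, about 15% of
frames; frames where only one border is hard (e.g. the blood-pool peak, when
the endocardial border is crisp) stay grade 0.

The simulated segmenter stands in for a trained patch-based network.  Its
base output is the (blurred, slightly deflated) ground-truth probability, so
with all error magnitudes zero the pipeline reproduces the ground truth and
the dQC map vanishes.  Three seeded error mechanisms exercise the dQC
pathways:

* a per-patch-origin additive bias — the same pixel receives different
  probabilities from different patches, which is exactly the disagreement the
  dQC map measures;
* on grade-1 frames, each patch independently (with probability
  ``difficulty_error_rate``) produces a frame-consistent defect: two opposite
  angular sectors of the ring dropped to zero (breaking the ring into two
  arcs — a non-contiguity failure), or blood-pool probabilities leaking to
  foreground — so hard frames yield both corrupted consensus segmentations
  and strong inter-patch disagreement;
* per-pixel Gaussian noise.

Everything is deterministic given (patch origin, frame, seeds), as the
segmenter contract requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .patch_ops import ImageSeries, MaskSeries, Segmenter

__all__ = [
    "PhantomSpec",
    "PhantomBundle",
    "SimSegmenterSpec",
    "gamma_variate",
    "generate_phantom",
    "make_sim_segmenter",
]


def gamma_variate(t: np.ndarray, delay: float, time_to_peak: float, alpha: float) -> np.ndarray:
    """Normalized gamma-variate bolus curve, peak 1 at ``delay + time_to_peak``.

    The standard parametric shape for contrast-agent concentration:
    ``((t-t0)/tp)^a * exp(a*(1-(t-t0)/tp))`` for ``t > t0``, 0 before arrival.
    """
    t = np.asarray(t, dtype=np.float64)
    x = (t - delay) / time_to_peak
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = x[pos] ** alpha * np.exp(alpha * (1.0 - x[pos]))
    return out


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, dynamics and noise of one synthetic DCE slice.

    Defaults match the working resolution of a localized perfusion series
    (128 x 128 pixels, 25 frames) with a myocardial ring of inner radius 12
    and outer radius 20 pixels, ~3-pixel breathing excursion, and enhancement
    amplitudes chosen so the blood pool peaks early at roughly twice the
    myocardial enhancement.
    """

    M: int = 128
    N: int = 128
    T: int = 25
    center: Tuple[float, float] = (64.0, 64.0)
    r_inner: float = 12.0
    r_outer: float = 20.0
    breath_amplitude: float = 3.0   # pixels, row direction (superior-inferior)
    breath_period: float = 9.0      # frames
    jitter: float = 0.5             # pixels, per-frame seeded random offset
    background: float = 0.3         # arbitrary intensity units
    bp_amplitude: float = 2.0
    bp_delay: float = 2.0
    bp_time_to_peak: float = 4.0
    bp_alpha: float = 3.0
    myo_amplitude: float = 0.9
    myo_delay: float = 5.0
    myo_time_to_peak: float = 7.0
    myo_alpha: float = 3.0
    noise_sigma: float = 0.04
    psf_sigma: float = 0.8          # in-plane point-spread blur, pixels
    grade_threshold: float = 0.12   # max boundary contrast below which a frame is grade 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.r_inner < self.r_outer < min(self.M, self.N) / 2):
            raise ValueError("need 0 < r_inner < r_outer < min(M, N)/2")
        if self.T < 2:
            raise ValueError("need T >= 2")


@dataclass(eq=False)
class PhantomBundle:
    """One generated slice: images, truth masks, difficulty grades, metadata."""

    series: ImageSeries
    gt: MaskSeries
    blood_pool: MaskSeries
    grades: np.ndarray          # (T,) int, 1 = high-grade difficulty
    contrast: np.ndarray        # (T,) boundary-contrast statistic (max of endo/epi contrast)
    centers: np.ndarray         # (T, 2) ring center per frame
    spec: PhantomSpec


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Generate one synthetic DCE slice with ground truth and grades.

    Deterministic given ``spec`` (including its seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xD0]))
    t = np.arange(spec.T, dtype=np.float64)
    bp_curve = spec.background + spec.bp_amplitude * gamma_variate(
        t, spec.bp_delay, spec.bp_time_to_peak, spec.bp_alpha
    )
    myo_curve = spec.background + spec.myo_amplitude * gamma_variate(
        t, spec.myo_delay, spec.myo_time_to_peak, spec.myo_alpha
    )
    # Boundary contrasts from the noise-free curves: endocardial (myocardium vs
    # blood pool) and epicardial (myocardium vs background).  A frame is hard
    # when BOTH are weak, i.e. when the maximum is small.
    contrast = np.maximum(np.abs(myo_curve - bp_curve), np.abs(myo_curve - spec.background))
    grades = (contrast < spec.grade_threshold).astype(np.int64)

    rows, cols = np.mgrid[0 : spec.M, 0 : spec.N].astype(np.float64)
    drift_r = spec.breath_amplitude * np.sin(2.0 * np.pi * t / spec.breath_period)
    drift_c = 0.4 * spec.breath_amplitude * np.sin(2.0 * np.pi * t / spec.breath_period + 1.0)
    jit = spec.jitter * rng.standard_normal((spec.T, 2))

    img = np.empty((spec.M, spec.N, spec.T), dtype=np.float64)
    gt = np.empty((spec.M, spec.N, spec.T), dtype=np.uint8)
    bp = np.empty((spec.M, spec.N, spec.T), dtype=np.uint8)
    centers = np.empty((spec.T, 2), dtype=np.float64)
    for k in range(spec.T):
        cr = spec.center[0] + drift_r[k] + jit[k, 0]
        cc = spec.center[1] + drift_c[k] + jit[k, 1]
        centers[k] = (cr, cc)
        d = np.hypot(rows - cr, cols - cc)
        ring = (d >= spec.r_inner) & (d <= spec.r_outer)
        pool = d < spec.r_inner
        gt[:, :, k] = ring
        bp[:, :, k] = pool
        frame = np.full((spec.M, spec.N), spec.background)
        frame[pool] = bp_curve[k]
        frame[ring] = myo_curve[k]
        if spec.psf_sigma > 0:
            frame = gaussian_filter(frame, spec.psf_sigma)
        img[:, :, k] = frame
    if spec.noise_sigma > 0:
        img += spec.noise_sigma * rng.standard_normal(img.shape)

    return PhantomBundle(
        series=ImageSeries(img),
        gt=MaskSeries(gt, role="ground-truth"),
        blood_pool=MaskSeries(bp, role="ground-truth"),
        grades=grades,
        contrast=contrast,
        centers=centers,
        spec=spec,
    )


@dataclass(frozen=True)
class SimSegmenterSpec:
    """Error model of the simulated patch segmenter.

    ``base_scale`` deflates the blurred ground-truth probability away from the
    clip boundary at 1 so that the per-patch bias stays observable in the
    interior of the ring (a probability pinned at 1.0 would hide any positive
    bias behind clipping).
    """

    blur_sigma: float = 1.5
    base_scale: float = 0.92
    patch_bias_sigma: float = 0.05
    difficulty_error_rate: float = 0.6
    dropout_half_angle: float = 0.45   # radians; angular half-width of a dropped sector
    leak_probability: float = 0.9      # foreground probability written into the blood pool
    noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("blur_sigma", "patch_bias_sigma", "difficulty_error_rate", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def make_sim_segmenter(bundle: PhantomBundle, spec: SimSegmenterSpec) -> Segmenter:
    """Build a deterministic simulated segmenter for one phantom slice.

    The returned callable honors the segmenter contract: it maps a
    ``(K, K, T)`` patch (any ``K``) plus its origin to probabilities in
    ``[0, 1]`` and is bit-reproducible per (origin, seeds), so repeated
    invocation — as the streaming dQC pass does — is safe.
    """
    M, N, T = bundle.series.shape
    base = np.empty((M, N, T), dtype=np.float64)
    gt_float = bundle.gt.data.astype(np.float64)
    for k in range(T):
        frame = gt_float[:, :, k]
        if spec.blur_sigma > 0:
            frame = gaussian_filter(frame, spec.blur_sigma)
        base[:, :, k] = spec.base_scale * frame

    grade1 = np.flatnonzero(bundle.grades == 1)
    # Frame-keyed defect geometry, shared by every defective patch at that
    # frame: a consistent failure location is what drags the patch-averaged
    # probability below threshold and breaks the consensus ring.
    sector_mask = {}
    defect_is_dropout = {}
    rows, cols = np.mgrid[0:M, 0:N].astype(np.float64)
    for k in grade1:
        frng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xF0, int(k)]))
        phi = frng.uniform(0.0, 2.0 * np.pi)
        defect_is_dropout[int(k)] = bool(frng.random() < 0.5)
        ang = np.arctan2(rows - bundle.centers[k, 0], cols - bundle.centers[k, 1])
        # Two opposite wedges: removing a single wedge leaves a connected
        # C-shape, so a non-contiguous (two-arc) failure needs both.
        d1 = np.abs(np.angle(np.exp(1j * (ang - phi))))
        d2 = np.abs(np.angle(np.exp(1j * (ang - phi - np.pi))))
        sector_mask[int(k)] = np.minimum(d1, d2) <= spec.dropout_half_angle

    bp_bool = bundle.blood_pool.data.astype(bool)

    def seg(patch: np.ndarray, origin: Tuple[int, int]) -> np.ndarray:
        r, c = origin
        k_rows, k_cols, k_t = patch.shape
        if k_t != T:
            raise ValueError(f"patch has {k_t} frames, phantom has {T}")
        block = base[r : r + k_rows, c : c + k_cols, :].copy()
        if spec.patch_bias_sigma > 0:
            bias_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1, r, c]))
            block += bias_rng.normal(0.0, spec.patch_bias_sigma)
        if grade1.size and spec.difficulty_error_rate > 0:
            draw_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 2, r, c]))
            draws = draw_rng.random(T) < spec.difficulty_error_rate
            for k in grade1:
                if not draws[k]:
                    continue
                if defect_is_dropout[int(k)]:
                    sel = sector_mask[int(k)][r : r + k_rows, c : c + k_cols]
                    block[:, :, k][sel] = 0.0
                else:
                    sel = bp_bool[r : r + k_rows, c : c + k_cols, k]
                    block[:, :, k][sel] = spec.leak_probability
        if spec.noise_sigma > 0:
            noise_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 3, r, c]))
            block += noise_rng.normal(0.0, spec.noise_sigma, size=block.shape)
        return np.clip(block, 0.0, 1.0)

    return seg


def phantom_batch(n: int, seed: int, spec: PhantomSpec | None = None) -> list[PhantomBundle]:
    """Generate ``n`` phantoms with per-slice seeds derived from ``seed``."""
    template = spec if spec is not None else PhantomSpec()
    # keep derived seeds well below 2**31
    return [
        generate_phantom(replace(template, seed=(seed * 1000 + i) % (2**31 - 1)))
        for i in range(n)
    ]
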