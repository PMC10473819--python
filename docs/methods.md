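# Methods

## Patch aggregation and the dQC map

A dynamic series `I ∈ R^{M×N×T}` is decomposed by a sliding window of
spatial size `K×K` and stride `w`; patches always span the full time axis
(the segmenter is spatiotemporal, not frame-by-frame).  Anchor rows are
`{0, w, 2w, …}` capped at `M−K`; when `(M−K) % w ≠ 0` the flush anchor `M−K`
is appended so the bottom/right edges are always covered (with the default
geometry — 128, K=64, w ∈ {16, 2} — the flush anchor coincides with the
regular lattice, so nothing changes there).  Every pixel is therefore covered
by at least one patch; a corner pixel by exactly one.

Aggregation is per pixel over the covering patches `Γ_{m,n}`:

* **mean** → binarized at an *inclusive* 0.5 threshold → the mask `S`;
* **population standard deviation** (divisor `|Γ_{m,n}|`, not `|Γ|−1`) → the
  dQC map `M`.  The population divisor makes single-coverage pixels a
  well-defined 0 instead of 0/0.

The two passes use different grids: segmentation at `w_S = 16` (cheap),
disagreement at `w_M = 2` (each interior pixel seen by up to 1024 contexts).
They are independent inference passes; coarse-grid outputs are never reused
on the dense grid.  A warning (not an error) is raised if `w_M > w_S`.

**Numerics.**  The std is computed in two passes (aggregate mean first, then
squared deviations from it), which is exact to ~machine epsilon even when the
variance is tiny — a one-pass `E[x²]−E[x]²` would cancel catastrophically.
The dense pass streams: the segmenter is invoked twice per patch instead of
materializing the full probability stack (~0.9 GB at default geometry); the
segmenter contract requires determinism precisely so this is valid.  When all
covering patches agree, the computed std is not an exact 0 but an
O(eps) residue of float accumulation (≤1e−12 in all tests); single-coverage
pixels are exactly 0.  Since probabilities live in `[0,1]`, the map is
bounded by 0.5 everywhere.

## Uncertainty metrics

With `A(t)` the predicted segmentation area of frame `t`:
`Q_pixel = M/A(t)` per location, `Q_frame(t) = ‖M(t)‖_F / A(t)`,
`Q_slice = mean_t Q_frame(t)`.  Area normalization makes scores comparable
across heart sizes; it also means each series defines its own scale, which is
why the difficulty analysis builds one classifier per slice rather than
pooling scores.

**Empty-mask frames.**  The normalization is undefined at `A(t)=0`.  Such
frames use divisor `max(A,1)` and carry a `degenerate` flag; referral ranking
forces flagged frames to the front unconditionally.  An empty myocardium is
anatomically infeasible — the flag guarantees it reaches the expert rather
than hiding behind a finite score.  `Q_slice` averages over all frames,
degenerate ones at their flagged values.

## Evaluation

Dice is computed per frame (2D) and pooled over all `M×N×T` voxels
(2D+time); two empty masks agree (Dice 1), an empty prediction against a
non-empty truth scores 0.  A frame *fails* when its foreground is empty or
not a single 8-connected component; 8-connectivity was chosen so a
one-pixel-wide diagonal ring segment does not count as broken.  The
difficulty AUC uses the Mann–Whitney convention (ties worth 0.5 per pair) via
`sklearn.metrics.roc_auc_score`, one ROC per slice; single-class slices are
excluded with a logged warning, and the summary is mean ± std over included
slices.

## Referral harness

The budget is `round(fraction × total frames)` (half-up).  The dQC arm ranks
frames by `Q_frame` pooled **globally** across slices (degenerate first, ties
broken by (slice, frame) ascending); a `per_slice` option ranks within each
slice instead — the global pool is the default because the budget in the
motivating scenario is a fraction of the whole test set.  The random arm
draws a uniform sample of the same size, repeated `n_mc` times (default 100)
with per-run seeds derived from the experiment seed; its summary averages the
per-run statistics.  Post-correction scores are cumulative — recomputed over
*all* frames, corrected or not.

Two expert policies: **oracle** replaces every referred frame with ground
truth (used for bounding: full budget + oracle ⇒ Dice 1, prevalence 0);
**reluctant** (the headline default) corrects a referred frame only if it
judges it erroneous — non-contiguous or empty foreground, overlap with the
known blood pool above 10% of the predicted area, or 2D Dice below τ = 0.6.
The reluctance mirrors how a real reader leaves acceptable contours alone,
and makes the "fraction of referred frames actually corrected" statistic
meaningful.

## Synthetic phantom

One slice is a ring (inner radius 12 px, outer 20 px on a 128×128 grid, 25
frames) around a blood-pool disk.  Intensities follow gamma-variate curves
`((t−t₀)/t_p)^α exp(α(1−(t−t₀)/t_p))` on a 0.3 background: blood pool delay
2, time-to-peak 4, amplitude 2.0; myocardium delay 5, time-to-peak 7,
amplitude 0.9 (the myocardium enhances later and ~2× weaker, as tissue does
after the bolus transits the ventricle).  The ring center follows a sinusoid
(amplitude 3 px, period 9 frames, mostly superior–inferior) plus 0.5 px
seeded jitter; frames get a 0.8 px point-spread blur and σ = 0.04 Gaussian
noise.  Everything is deterministic given the spec seed.

**Difficulty grades.**  A frame is grade 1 when *both* borders are weak:
`max(|myo−blood|, |myo−background|) < 0.12` on the noise-free curves.  (The
max, not the min: one crisp border suffices for grade 0.)  The threshold was
calibrated once against the default curves to flag ≈15% of frames (4/25: the
pre-contrast frames and the washed-out tail) and then frozen.

**Simulated segmenter.**  Base output = blurred (σ = 1.5) ground-truth
probability scaled by 0.92 — the deflation keeps interior probabilities off
the clip boundary at 1 so additive per-patch bias remains observable.  Error
mechanisms, all seeded and keyed by patch origin and frame: (a) a scalar
`N(0, patch_bias_sigma)` bias per patch origin (default 0.05) — the
disagreement generator; (b) on grade-1 frames, per patch with probability
`difficulty_error_rate` (default 0.6), a frame-consistent defect: either two
opposite angular wedges of the ring zeroed (one wedge leaves a connected
C-shape; two break the ring into two arcs — a genuine non-contiguity
failure) or blood-pool pixels raised to 0.9 (a leakage failure); (c) pixel
noise σ = 0.02.  With rate 0.6, the patch-averaged probability inside a
dropped wedge is ≈0.92×0.4 < 0.5, so defects survive consensus aggregation —
hard frames end up with both corrupted masks and high `Q_frame`.

**What a green test does and does not establish.**  The phantom has sharp
two-tissue contrast, a perfectly annular target, rigid in-plane motion and
white noise; real DCE series have coil shading, through-plane motion,
papillary muscles and non-annular pathology, and a real DNN's error
correlations across patches are unknown.  Green tests establish that the
dQC machinery is computed correctly and that its referral logic beats random
selection *when corruption is concentrated in identifiable frames and
expressed as inter-patch disagreement* — the mechanism claim, not a clinical
performance claim.  Headline clinical numbers (external-dataset Dice, 16.2%
failure prevalence, AUC 0.847) depend on private data and trained weights and
are not reproduced here; the harness reproduces their *directions*.

## Defaults that matter

| parameter | default | meaning |
|---|---|---|
| `K` | 64 px | patch edge; patches span all `T` frames |
| `w_S` | 16 px | segmentation-pass stride |
| `w_M` | 2 px | dQC-pass stride (denser ⇒ more contexts per pixel) |
| threshold | 0.5, inclusive | mask binarization |
| `fraction` | 0.1 | referral budget over all frames |
| `n_mc` | 100 | random-arm Monte Carlo repeats (20 in the test suite, for time) |
| `τ` | 0.6 | reluctant expert's Dice floor |
| blood-pool overlap | 0.1 | reluctant expert's leakage criterion |

## Known limitations

Single-slice (2D+time) only — no multi-slice 3D patches; no network training
or GPU inference; NIfTI/raw I/O only (no DICOM); the blood-pool leakage
criterion needs the blood-pool mask, which only the synthetic world provides;
`Q` metrics are relative scores, not calibrated error probabilities.
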