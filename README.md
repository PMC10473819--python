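# dynqc

Dynamic quality control (dQC) for patch-based segmentation of dynamic
(2D+time) image series, with a human-in-the-loop referral harness.

## The problem

Free-breathing dynamic contrast-enhanced (DCE) cardiac MRI produces hundreds
of time frames per exam; segmenting the myocardium in every frame by hand is
impractical, and automated (DNN) segmentations fail silently on hard frames —
low-contrast wash-in/out phases, residual breathing motion.  A clinical
pipeline needs a *test-time* quality-control signal that localizes, in both
space and time, where a segmentation is likely wrong, so that a human expert
with a limited time budget reviews exactly those frames.

`dynqc` implements a model-agnostic answer for patch-based segmenters.  The
dynamic image `I ∈ R^{M×N×T}` is decomposed into overlapping spatiotemporal
patches `(K×K×T)` by a sliding window with spatial stride `w`.  Each pixel
`(m, n)` is covered by a set `Γ_{m,n}` of patches, each of which assigns it a
probability `p^i_{m,n}(t)`.  Two aggregations of the same patch outputs give:

* the **segmentation** (computed on a coarse grid, stride `w_S`):

  `S_{m,n}(t) = 1` iff `mean_{i ∈ Γ_{m,n}} p^i_{m,n}(t) ≥ 0.5`;

* the **dQC map** (on a dense grid, stride `w_M < w_S`):

  `M_{m,n}(t) = std_{i ∈ Γ_{m,n}} p^i_{m,n}(t)`,

  the inter-patch disagreement at each space-time location — zero where every
  spatial context yields the same answer, up to 0.5 where contexts conflict.

From the map, three metrics normalized by the predicted segmentation area
`A(t) = Σ_{m,n} S_{m,n}(t)`:

* `Q_pixel(m,n,t) = M_{m,n}(t) / A(t)`
* `Q_frame(t) = ‖M(·,·,t)‖_F / A(t)` — the per-frame uncertainty
* `Q_slice = (1/T) Σ_t Q_frame(t)` — the per-series score

`Q_frame` ranks frames for referral: given a budget (10% of all frames by
default), the top-ranked frames go to an (simulated) expert who corrects the
ones that are genuinely wrong — non-contiguous or empty masks, blood-pool
leakage, low Dice.  The harness compares this arm against random referral
over Monte Carlo repeats.

Because no public dataset or trained network ships with the method, the
package includes a first-class synthetic phantom: a ring-shaped myocardium
with gamma-variate contrast dynamics, breathing displacement and noise, plus
a simulated patch segmenter whose seeded, patch-dependent errors exercise
every dQC pathway.  Frames are difficulty-graded by a contrast rule
(grade 1 ≈ 15% of frames), and the segmenter's corruption is linked to the
hard frames — so the phantom reproduces, in direction, the regime the method
is designed for.

## Worked example

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

prints (8 synthetic slices of 128×128×25, patch size 64, `w_S=16`, `w_M=2`,
10% budget, reluctant expert, 20 Monte Carlo random runs):

```
slices: 8   frames: 200   budget: 20
baseline: Dice(2D+time) 0.962 +/- 0.008  failure prevalence 8.5%  corrected 0.0%
  random: Dice(2D+time) 0.965 +/- 0.009  failure prevalence 7.8%  corrected 14.0%
     dqc: Dice(2D+time) 0.976 +/- 0.011  failure prevalence 0.0%  corrected 90.0%
selected-frame initial 2D Dice: dQC 0.835  random 0.964
difficulty AUC: 1.000 +/- 0.000 over 8 slices
```

Reading it: the uncorrected baseline leaves 8.5% of frames with a broken
(non-contiguous) ring.  Spending the same 20-frame budget, random referral
barely moves the cumulative Dice (the expert finds little to fix — only 14%
of referred frames are corrected), while dQC-guided referral sends the expert
frames that are genuinely bad (initial 2D Dice 0.835 vs 0.964 for random;
90% get corrected), eliminating the failures and raising the cumulative
2D+time Dice.  The per-slice AUC shows `Q_frame` separating rule-graded hard
frames from easy ones.

The same experiment is available as a CLI:

```bash
dynqc phantom --out data/ --n-slices 5 --seed 1      # synthetic dataset
dynqc segment --phantom data/ --slice 0 --out seg.nii.gz
dynqc qc --phantom data/ --slice 0 --out qc/          # dQC map + metrics
dynqc hitl-sim --out run/ --n-slices 5 --seed 1       # referral experiment
dynqc evaluate --pred seg.nii.gz --gt data/gt_00.nii.gz
```

Library users plug their own segmenter — any callable mapping a `(K, K, T)`
patch plus its `(row, col)` origin to probabilities in `[0, 1]` — into
`dynqc.segment_series` and `dynqc.compute_dqc_map`.

## What `scripts/acceptance.py` does

It re-runs the package's main computation from scratch for a given `--seed`:
generates the seeded phantom dataset, segments each slice, computes dQC maps
and frame metrics, runs the budgeted referral experiment and the per-slice
difficulty-AUC analysis, prints the summary above, and writes the results
manifest to `--out`.

See `docs/methods.md` for the model, parameter defaults, numerical choices
and limitations.
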