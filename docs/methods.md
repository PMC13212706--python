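# Methods

This note documents the models, algorithms and design choices behind
`lesionssl`: a semi-supervised, mean-teacher pipeline for detecting rare
lesions in partially labeled multi-sequence 3D imaging cohorts, together
with its lesion-level evaluation and statistical-comparison stack.

## Problem setting

The target regime is a screening-style cohort: most cases are negative; a
minority are positive (pathology-confirmed), and only a fraction of the
positives carry voxel-wise expert masks, while the rest are known positive
from reports but unannotated.  Three supervision strategies are compared:

1. **supervised** — train on the human-annotated positives plus all
   negatives (negatives are supervised as an all-background mask, so the
   model learns lesion-free appearance);
2. **semi-supervised** — additionally use the report-positive unannotated
   cases: a supervised model first pseudo-annotates them, and a fresh model
   is trained on the enlarged set with mean-teacher consistency;
3. **fully supervised** — the upper bound: every positive with its true
   mask.

## Mean-teacher mechanics

Two structurally identical networks are maintained.  The **student** `m_s`
is trained by backpropagation; the **teacher** `m_t` follows by an
exponential moving average, `m_t ← α·m_t + (1−α)·m_s` after every optimizer
step.  Each training volume is fed to the student directly (plus additive
intensity noise) and to the teacher after a randomly drawn invertible
spatial transform φ; the teacher's probability map is mapped back through
φ⁻¹ and a voxel-wise mean-squared **consistency loss** `L_con` penalises
student–teacher disagreement on the original grid.  The total loss is
`L_seg + λ(t)·L_con`, where `λ(t)` follows the standard sigmoid-shaped ramp
`λ_max · exp(−5(1 − t/T)²)` over the first 40% of steps (`λ_max = 1` by
default) so that early, noisy teacher outputs do not dominate.

φ is restricted to transforms with *exact* voxel-level inverses — axis
flips, right-angle rotations in axis-aligned planes, and integer-voxel
translations — because the consistency loss compares aligned voxels and any
interpolated transform would inject resampling error into the target.
Translations lose a border strip; those voxels are tracked by a validity
mask and excluded from `L_con` rather than wrapped around (wrap-around
would fabricate anatomy).  Intensity augmentation (additive Gaussian noise,
SD 0.05 by default) is applied on both branches independently and is not
part of φ since it needs no inverse.

The supervised term `L_seg` is focal cross-entropy plus soft Dice on the
foreground channel, equally weighted.  The focal exponent (γ = 2) and an
optional lesion-class weight (default 1) up-weight the rare lesion voxels
against the ~95–99% background.  Cases without any usable mask (withheld
positives before pseudo-labeling) contribute only `L_con`.

**Pseudo-labeling** is two-stage and frozen: the supervised model's
probability maps on the report-positive cases are post-processed by the
same candidate extractor used for evaluation, and the retained candidates
become fixed masks (status `pseudo`).  If no candidate survives the size
filter, the largest connected component above half the map maximum is kept
instead, so that every known-positive case receives a nonempty mask where
possible; a case with an identically zero map stays unsupervised and is
logged.  Negatives never receive pseudo-labels.  There is no online
refresh — this matches the two-stage design the strategy comparison needs
(the pseudo-labeler *is* the supervised baseline).

### Backbone and training schedule

The backbone is a small 3D U-Net implemented directly in numpy with
hand-written backpropagation (3×3×3 convolutions via shifted channel-mixing
tensordots, instance normalization, ReLU, 2× average pooling,
nearest-neighbour upsampling, skip connections, per-voxel 2-class softmax),
optimised with Adam.  The semi-supervised mechanics are architecture-
agnostic, so the backbone is deliberately minimal and fully configurable
(`depth` resolution levels, `base_width` channels, convolutions per block,
normalization).  Defaults — depth 3, width 4, one convolution per block,
learning rate 1e-2, batch 8, 30 epochs of whole-volume training — are sized
so a full strategy comparison runs on one CPU core in minutes.  Whole
volumes are used rather than patches because the phantom grids are small.

The EMA decay default is α = 0.95.  The decay sets the teacher's averaging
horizon in *steps* (≈ 1/(1−α)); with the few-hundred-step schedules used
here, α = 0.99 would leave the teacher dominated by its random
initialization (0.99³⁰⁰ ≈ 5% of the initial weights still present after 300
steps, and a lagging, noisy consistency target throughout), which we
observed to destabilise training.  α = 0.95 gives a ≈ 20-step horizon, the
same *relative* horizon (a few percent of total steps) that α ≈ 0.99–0.999
gives the multi-thousand-step schedules typical of GPU training.  Inference
uses the teacher, following mean-teacher convention.

Reproducibility: initialization, batch order, transform draws and noise
draws come from four independent streams spawned from one seed; two runs
with the same seed produce bit-identical loss traces and weights.

## Synthetic phantom cohorts

No public simulator exists for this regime, so the package ships its own.
Each case is three co-registered channels mimicking the qualitative
contrast of T2-weighted, ADC and high-b diffusion MRI: an ellipsoidal
"organ" (semi-axes 0.4 of the grid) over a darker exterior, a smooth
Gaussian texture field (σ = 3 voxels), and iid Gaussian noise
(`noise_sd`, default 0.1).  Lesions are unions of 1–3 random ellipsoids
(radii 2–5 mm) placed inside the organ; inside the lesion support the
ADC-like channel is *depressed* and the DWI-like channel *elevated* by
`contrast × noise_sd` (the T2w-like channel mildly depressed, factor 0.5),
so a single scalar controls detectability relative to the noise floor.
Ground-truth lesions are the 26-connected components of the union support
(touching ellipsoids merge, exactly as a component-based detector would see
them), labeled in decreasing-volume order.

Cohort structure mirrors the partially annotated regime: default prevalence
0.3 and human-label fraction 0.5 echo a cohort in which roughly 28% of
cases are positive and roughly half of the positives are expert-annotated.
Counts follow `rint(prevalence·n_cases)` and `rint(fraction·n_pos)`
(ties-to-even), making them exact and testable.  All draws are split into a
cohort-level stream and per-case streams keyed by `[seed, 1000+index]`, so
cohorts are bit-reproducible and individual cases regenerable in isolation.

What the phantom does **not** emulate: MRI physics (bias fields, coil
profiles), registration error between sequences, scanner/field-strength
domain shift, anatomical zonal structure, and realistic lesion-shape or
intensity distributions.  Passing tests on phantoms therefore demonstrates
the *mechanics* — supervision strategies, consistency, pseudo-labeling,
metrics and statistics — not clinical-grade detection performance.

The default grid is 32×48×48 at 1 mm isotropic spacing.  The test suite and
the acceptance script run on 16×24×24 grids with 30–40-case cohorts — sizes
chosen so the full study (three strategies × several seeds) completes in
minutes on one CPU core with the numpy backbone; the pipeline is
grid-agnostic.

## Evaluation

- **Candidate extraction**: threshold each probability map at
  `θ · max(map)` (θ = 0.4 by default), 3D connected components (26- or
  6-connectivity; 26 default), discard components below `min_voxels`
  (default 10; 5 on the small test grids), score each candidate by its
  maximum probability.  The per-case dynamic threshold follows the
  established challenge evaluation practice of thresholding relative to the
  case maximum; θ and `min_voxels` are recorded in every report since
  dialects differ.
- **Matching**: a candidate is a true positive if its IoU with an unmatched
  ground-truth lesion strictly exceeds 0.10; matching is greedy in
  descending confidence and one-to-one per lesion (ties broken by larger
  IoU, then lower component id).
- **Lesion-level AP**: non-interpolated area under the precision–recall
  curve over all detections pooled across the cohort and ranked by
  confidence.
- **Patient-level AUC**: each case is scored by its maximum voxel
  probability; AUC is the normalised Mann–Whitney statistic (ties ½).
- **Overall score**: the arithmetic mean of AUC and AP.
- **Fixed-FPR operating point**: the threshold is the smallest observed
  score whose strict-exceedance FPR is ≤ the target (0.50), so the achieved
  FPR never exceeds the target; missed positives are those at or below the
  threshold.

## Statistics

Paired model comparisons on a shared cohort use:

- **percentile bootstrap CIs** (case-level resampling, n-out-of-n, B =
  10,000 by default, 2.5/97.5 percentiles).  Resamples on which a metric is
  undefined (single-class draw for AUC, lesion-free draw for AP) are
  redrawn so every interval rests on B effective replicates; if more than
  half of attempted draws are undefined the computation aborts.  Percentile
  rather than BCa: the simplest interval consistent with standard practice.
- **DeLong's test** for the difference of correlated AUCs, in the fast
  midrank (structural-component) form; two-sided normal p-value.  Identical
  score vectors report difference 0, p = 1.
- **paired bootstrap test for AP differences**: resample cases, recompute
  `AP_A − AP_B` per replicate, `p = 2·min(frac ≤ 0, frac ≥ 0)` floored at
  1/B (a finite resample cannot support p = 0).  Case-level (not
  lesion-level) resampling preserves the paired design.
- **Holm–Bonferroni** step-down adjustment over the tested family.  Note
  Holm controls the family-wise error rate, not the false discovery rate;
  it is implemented (via statsmodels) as standard Holm.

Two-sided tests throughout.

## Numerical notes and degenerate inputs

Probabilities are clamped at ε = 1e-7 inside the focal term; Dice uses
smoothing 1e-5, which makes the all-background prediction exactly optimal
on negative cases.  An all-zero probability map yields no candidates and
patient score 0.  AP without any ground-truth lesion, AUC/fixed-FPR
analysis on a single-class cohort, and a withheld-positive case reaching
the supervised loss are explicit errors rather than silent zeros.
Instance normalization refuses single-voxel bottleneck grids, where its
statistics are degenerate.

## Known limitations

- The numpy backbone is orders of magnitude slower than a GPU framework;
  it exists to make the SSL mechanics runnable and testable end to end,
  not to train clinical models.
- Pseudo-label quality gates the semi-supervised strategy, exactly as in
  the real regime: if the supervised baseline is too weak to localise
  lesions, pseudo-labels add patient-level signal but little voxel-level
  precision (visible as AUC gains without AP gains on hard phantoms).
- The phantom's difficulty scalar conflates lesion conspicuity across
  channels; real cohorts have per-sequence, per-lesion variability.
- Whole-volume training assumes the grid fits in memory; no patch sampler
  is provided.
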