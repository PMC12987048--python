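# Methods

This note documents the models, conventions, and design choices behind
`frontaleeg`, including the points where the procedure was genuinely open
and a decision had to be fixed.

## Signal model and preprocessing

The pipeline assumes continuous three-channel prefrontal EEG (Fp1, Fz,
Fp2) sampled at 250 Hz under an eyes-closed resting protocol.
Preprocessing is deliberately minimal: per-channel z-scoring over the full
recording, overlapped windowing, and window-level quality control —
nothing else. Two considerations drive this: a three-channel montage has
too few spatial degrees of freedom for reliable blind source separation
(ICA/ASR), and parameter-heavy cleaning introduces dataset-specific bias
that hurts cross-device transfer. Because z-scoring removes scale, readers
do not rescale native units on ingest (microvolts and arbitrary amplifier
units behave identically downstream).

Conventions: sample indices are 0-based; windows are half-open
`[start, start + L)`; the stride is `S = round(L·(1 − p/100))`, which is
exact for every tested (L, p) pair and only rounds for unusual user
inputs. Recordings shorter than one window are excluded (an outcome, not
an error).

Quality control removes windows that contain non-finite values, a channel
with variance ≤ 1e−12, or a saturation plateau. "Obvious
clipping/saturation" has no unique operational definition; the rule used
here flags a run of ≥ 25 consecutive samples (0.1 s at 250 Hz) within
1e−12 of the channel's recording-level minimum or maximum — the canonical
signature of a rail-pinned amplifier — with the run length configurable.
A recording-level exclusion threshold (default: more than 20 % of windows
removed) stands in for the protocol-level "contaminated recording" rule;
the definition is interpretive and exposed as a parameter.

## Features

Welch parameters are fixed, not user-tunable, in the canonical pipeline:
Hann taper, segment length 2·fs, overlap fs, constant detrend. At 250 Hz
this yields a 0.5 Hz grid, and every window length used here (≥ 1344
samples) contains at least one full segment.

Band edges are half-open `[lo, hi)` on the discrete grid with the last
band closed at 100 Hz, so the seven bands tile 0.5–100 Hz exactly. Band
and total power use the same rectangle rule (bin sum × Δf), making the
sum-to-one property of relative powers an algebraic identity rather than
an approximation. A consequence worth knowing: a Welch bin at a band edge
(say 13.0 Hz) collects spectral mass from `f ± 0.25 Hz`, so band fractions
estimated from sharply band-limited signals shift by up to a quarter-bin
relative to continuous-frequency expectations; the parameter-recovery
tests account for this.

Differential entropy uses the Gaussian closed form `½·ln(2πeσ²)` in nats,
with the window variance floored at 1e−12. It enters only the 3×8
per-channel map, not the global vector.

Moment conventions (unstated in most feature protocols, fixed here):
skewness is Fisher–Pearson, kurtosis is Pearson (non-excess; a Gaussian
scores 3), both bias-uncorrected. Ratio denominators are floored at 1e−12;
whether the original protocol floored them is unknowable from the outside,
and the floor only engages on degenerate windows that QC should have
removed.

## Synthetic cohorts

The generator emulates eyes-closed frontal EEG as stationary Gaussian
noise with a controlled spectrum: seven flat band plateaus whose
log-powers carry the class structure, a 1/f background (exponent 1.0,
weight 0.15), and a Gaussian alpha bump at 10 ± 1 Hz — the dominant
eyes-closed frontal feature. Channels are synthesized by rFFT-domain
shaping of white noise (exact spectral control, deterministic under seed).
Between-subject variation is a shared random effect on the log-power scale
(SD 0.20 by default) — multiplicative physiological variability that keeps
powers positive — plus per-band class scatter (SD 0.30) and small
per-channel jitter (SD 0.05).

The default class contrast encodes frontal slowing in the patient class:
relative θ up (+0.55 log units), low-γ up (+0.35), high-γ down (−0.65),
δ slightly down (−0.25). These signs make subject-level group analyses on
simulated cohorts reproduce the expected directions with large effect
sizes. `well_separated_spec` strengthens θ to +0.8 and high-γ to −0.9
(≥ 1 between-subject SD) for end-to-end pipeline checks.

What the generator does **not** model: eye-blink/EMG artifacts,
nonstationarity, volume conduction, alpha reactivity, or any nonlinear
structure. Passing tests on synthetic cohorts therefore demonstrate that
the pipeline recovers class-conditional *spectral* structure under
realistic between-subject variability — not that it handles real-world
artifacts or cross-device covariate shift.

## Networks and the NumPy engine

The three architectures (hybrid fusion, Conv1D-raw, Conv1D-SE) are built
on a small self-contained NumPy engine with explicit backward passes:
Conv1D ("same" padding, stride 1) via im2col, max pooling (floor on
non-divisible lengths), batch normalization over the channel axis,
inverted dropout, dense layers, global average pooling, and
squeeze-and-excitation gating (reduction 8, hidden width floored).
Gradients are verified against float64 directional derivatives in the test
suite. Computation is float32; weights use He-normal initialization; the
optimizer is Adam (the hybrid model's optimizer is not separately
specified anywhere, so Adam is used for consistency with the baselines).

Batch-norm running statistics are seeded from the first training batch and
updated with momentum 0.9. Subject-level EEG cohorts yield only a handful
of optimizer steps per epoch, and a slower EMA leaves inference statistics
stuck near initialization long after the batch statistics have moved —
the fastest single source of silent evaluation failure in this regime.

Fixed architectural constants: raw kernels (11, 7, 5), pool 4, map kernel
3, map pool 2, map embedding 128, global branch 64–32, post-embedding
dropout 0.5. The fusion-head dropout rate is not specified by the
protocol; it is fixed at 0.5 to match the raw-branch embedding dropout,
and is configurable. In the map branch the order is conv → pool → conv →
batch-norm → dropout → GAP ("interleaved" admits several readings; this
one is fixed and documented). The loss is soft-label cross-entropy with
per-sample weights `Σ_c y_c w_c`, which reduces exactly to sparse
class-weighted cross-entropy for hard labels and degrades gracefully under
MixUp.

Window length must be divisible by 4³ = 64 for the raw branch; 3840 gives
the chain 3840 → 960 → 240 → 60 with no implicit padding. The Conv1D-SE
default length 6000 floors its chain to 6000 → 1500 → 375 → 93.

## Augmentation

Hybrid recipe (training windows only): additive Gaussian noise
(σ = 0.01 z-units, p = 0.7), slow linear drift (ramp from 0 to d with
|d| ≤ 3 % of amplitude, p = 0.3), per-channel scaling 𝒩(1, 0.1²)
(p = 0.5), applied independently in that order; batch-level MixUp with
Beta(0.2, 0.2). Two ambiguities were fixed: (i) the drift's "signal
amplitude" reference is the channel's within-window peak-to-peak amplitude
(well-defined per window in z-units; per-recording amplitude would be the
alternative); (ii) MixUp mixes all three precomputed representations
(raw, map, global) with the same λ rather than recomputing features on
mixed raw signals — the features are nonlinear in the raw signal, and
mixing at the batch-input level is the standard reading. SE recipe:
noise σ = 0.02, joint circular shift up to ±10 % of L, scaling
𝒩(1, 0.05²), each with p = 0.5. The inference path contains no
augmentation call by construction.

## Training protocol

Subject-independent splitting is two-stage GroupShuffleSplit (dev/test
0.80/0.20, then train/val 0.85/0.15 within dev), deterministic per seed,
with a hard leakage audit (pairwise-disjoint subject sets) on every
produced split. Class weights are inverse-frequency, mean-normalized:
`w_c = N/(2·N_c)`.

The search space is exactly the cross-product of a fixed grid of candidate values
(three embedding sizes, three head widths, three learning rates, three
map dropouts, and two choices each of map filters, raw dropout schedule,
raw filters, and weight decay);
sampling is uniform without replacement. Stage 1 trains each sampled
configuration briefly with early stopping and ranks by best validation
accuracy; stage 2 retrains the top k longer and selects by
refinement-stage validation accuracy — short-run peaks are demonstrably
unstable under extended optimization, which is the motivation for this
rule — then refits the winner once on train+validation before the single
test evaluation.

Unstated knobs fixed here (all configurable): early-stop patience 15,
plateau patience 5, LR factor 0.5, LR floor 1e−5, hybrid batch size 64,
epoch budgets 40 (search) / 150 (refinement and final). Defaults are
consistent with a stepwise-decaying learning-rate trace over ~100+ epochs.

## Evaluation

MDD is the positive class throughout (sensitivity = MDD recall,
specificity = HC recall). MCC uses the 2×2 closed form with the 0/0 → 0
convention; it equals the phi coefficient, which the tests verify by
indicator-vector correlation on random tables. Wilson intervals use
z = Φ⁻¹(0.975), with bounds clipped to [0, 1] and guarded to bracket the
point estimate against floating-point rounding. Majority voting takes the
modal per-window argmax; exact ties resolve deterministically by argmax
over the vote-count vector (class index 0, HC); confidence is the mean
voted-class probability over all K windows. Window-level reports carry a
`descriptive_windows` flag: overlapped windows are serially correlated, so
window counts overstate the number of independent trials, and the
subject/recording is the unit of independent evidence.

Cliff's δ is computed exactly over all pairs; bootstrap CIs of the mean
use percentile resampling (default B = 4000, seeded). Group comparisons
aggregate window features per subject *before* computing δ or CIs, to
avoid pseudo-replication.

## Problem sizes used in the automated checks

The end-to-end acceptance check runs a 42-subject synthetic cohort
(21 HC / 21 MDD, 90 s each: 10 windows per subject at L = 3840, p = 50 %),
split 30 development / 12 held-out subjects, with a 2-trial search at 6
epochs, refinement of the top configuration at 12 epochs, and a 12-epoch
final fit — a deliberately small two-stage run that the package's own
training defaults scale up from. The pass bar is subject-level
majority-vote accuracy ≥ 0.9 on the 12 held-out subjects at a fixed seed.
Closed-form checks (metric stack, Wilson bounds, segmentation arithmetic)
run at exactly the reported tallies.

## Known limitations

- Stationary Gaussian synthesis cannot probe robustness to artifacts,
  drowsiness-related spectral drift, or device mismatch; claims about real
  cross-device transfer require real multi-site data.
- The NumPy engine is single-threaded BLAS-bound and intended for
  research-scale cohorts (hundreds of windows), not large-scale training.
- Batch-norm semantics differ slightly from framework defaults (first-batch
  seeding, momentum 0.9); checkpoints are therefore engine-specific.
- The window-level Wilson intervals inherit the independence caveat above:
  they quantify uncertainty over the windowed representation, not over
  subjects.
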