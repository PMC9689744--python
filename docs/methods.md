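# Methods

## Problem and pipeline

`pulsestage` classifies single cardiac cycles of PPG and ECG into the five
AHA blood-pressure categories, supervised by the per-beat extrema of a
simultaneously recorded ABP channel. The pipeline is: quality screening →
band-pass filtering (PPG 0.5–10 Hz, ECG 0.5–40 Hz) → R-peak detection →
R–R beat segmentation → resampling to 150 samples and min-max normalization
→ ABP-derived labeling → a concatenated dual-branch 1D CNN → 5-fold
cross-validated evaluation.

## Labeling

The AHA table mixes AND-joined rows (hypotension, normotension,
prehypertension) with OR-joined rows (stages 1 and 2), so the rows overlap:
125/85 mmHg satisfies both the prehypertension systolic clause and the
stage-1 diastolic clause. We resolve the overlap severe-first
(stage 2 → stage 1 → prehypertension), then hypotension before normotension
(its box is a strict subset). Readings outside every printed row
(SBP > 180, DBP > 120, or SBP < 90 with DBP ≥ 60 among others) are labeled
unclassifiable and dropped with a count; the table simply does not cover
them. Range endpoints are inclusive as printed. A brute-force
re-implementation of the table is kept in the tests and checked against the
production function over the full integer grid SBP ∈ [40, 200] ×
DBP ∈ [30, 130].

ABP is deliberately **not** band-pass filtered before SBP/DBP extraction:
filtering distorts absolute pressure values and labels need absolute mmHg.

## Preprocessing choices

- **Filter realization**: 4th-order Butterworth applied forward-backward
  (`sosfiltfilt`). Only the cut-offs are method-prescribed; zero phase keeps
  beat morphology and peak timing unshifted (the magnitude response is
  squared by the double pass).
- **R-peak detector**: squared derivative envelope smoothed over 120 ms,
  candidate peaks ≥ 0.25 s apart, adaptive gate at 0.4 × the rolling median
  of the last eight accepted envelope heights, followed by refinement to the
  local ECG maximum within ±80 ms. On 60 s synthetic records at 10 dB SNR it
  recovers ≥ 99% of beats within ±20 ms with ≤ 1% spurious detections (this
  is an acceptance test).
- **Beat window**: [R_k, R_{k+1}). Whether the cycle should instead be
  centered on R is ambiguous; starting at R keeps all three channels cut at
  identical indices, which is the property the fusion relies on.
- **Quality screen**: non-finite runs and any ≥ 2 s window whose per-channel
  range is below 10⁻³ of the channel's overall range are invalid; beats
  overlapping invalid samples are dropped. Non-finite samples are linearly
  interpolated in the working copy only so the filters stay finite.
- **Resampling**: cubic interpolation over a normalized time grid (linear
  for beats under 4 samples). It is exact on linear ramps, the identity on
  length-150 input, and idempotent on its own output grid.
- **Normalization**: per-segment min-max to [0, 1]. Input scaling is not
  method-prescribed, but mixing mV-scale ECG with arbitrary-unit PPG
  destabilizes training; per-segment scaling also removes inter-sensor gain,
  which forces the classifier to use shape rather than amplitude.
- **Split**: test = round(0.20·N) first, then validation = round(0.20 of the
  remainder), train = rest — this rounding order reproduces the
  9150/2288/2860 partition of a 14,298-segment pool. Splitting is
  segment-wise; when multiple records per subject exist, a subject-wise
  split (group by `source_record`) is the better practice and the fields to
  do it are carried on every segment.

## Network

Per branch, depth-d blocks of Conv1D(kernel 3, stride 1, same padding) →
ReLU → MaxPool(2, stride 2, floor), filters 8, 16, 32, 64, 128. At depth 5
an input of 150 samples pools to length 4 with 128 channels; flattening and
concatenating the two branches gives the fused width 2 × 4 × 128 = 1024.
Head: batch normalization on the fused vector → dense(64, ReLU) →
dense(5) softmax. Kernel size 3, pool 2, hidden width 64 and same-padding
are our choices where the method only says "small kernel size", "max
pooling" and "a hidden layer"; all four are constructor parameters.
Weights use seeded fan-in uniform initialization.

Training: Adam at learning rate 0.001, categorical cross-entropy, default
batch 32, up to 100 epochs with early stopping (patience 15) on validation
loss, checkpointing weights whenever validation loss improves and restoring
the checkpointed (not final-epoch) weights. Optional inverse-frequency class
weights exist but are off by default. A global seed fans out to split, fold,
init and shuffle seeds; the numpy implementation makes equal-seed runs
bit-identical.

Cross-validation pools the train and validation segments, builds k = 5
shuffled folds, and scores every fold's checkpointed model on one fixed
external test set that is asserted (by record/beat identity) never to
intersect the pool. The five test accuracies feed the confidence interval.

## Evaluation

Accuracy is trace/total of the 5×5 confusion matrix; per-class precision,
recall and F1 use the one-vs-rest collapse, with zero-denominator classes
scored 0 under a warning; macro scores are unweighted means. AUC is one-vs-
rest per class (trapezoidal/midpoint ties), classes without positives
excluded from the macro. The fold-accuracy interval is mean ± 1.96·s/√k
with the sample standard deviation, clipped to [0, 1]; a percentile
bootstrap is provided as an alternative. The input-mode comparison is a
one-way ANOVA whose response variable is ambiguous in the source protocol;
the default reading compares per-fold test accuracies across the three input
modes, and a per-segment feature variant (mean segment amplitude across the
five label groups) is also provided. Degenerate ANOVA input (all values
identical) returns (F, p) = (0, 1).

## Synthetic data

Real bedside recordings are not redistributable, so the generator emulates
the three channels with analytically controllable ground truth:

- **ECG**: five Gaussian bumps per beat (P, Q, R, S, T) with the R bump
  dominant; the stored R sample is the bump center, and the within-beat ECG
  maximum falls within ±10 ms of it in the clean case.
- **PPG**: a systolic wave plus a smaller delayed dicrotic wave, onset 0.2 s
  after each R (a typical pulse-arrival lag; configurable — the segmentation
  cuts all channels at the same indices regardless).
- **ABP**: the same two-component pulse family rescaled per R–R interval so
  the within-beat maximum and minimum equal that beat's jittered SBP/DBP
  targets exactly on the sampled grid.

Because the classifier never sees ABP, pressure must be encoded in PPG/ECG
*shape* for the task to be learnable. We map SBP monotonically into PPG
morphology (dicrotic amplitude 0.15 + 0.55·ŝ, dicrotic position
0.45 − 0.08·ŝ of the beat, systolic width 0.085 + 0.035·ŝ, where
ŝ = clip((SBP−60)/120, 0, 1)) and DBP into ECG morphology (T-wave amplitude
0.15 + 0.45·d̂, S-wave depth 0.10 + 0.15·d̂, d̂ = clip((DBP−40)/80, 0, 1)),
each with a small Gaussian shape jitter (σ = 0.01). The directions are
physiologically motivated (arterial stiffening advances and enlarges the
reflected wave; chronic pressure load alters repolarization), but the
mappings are a didactic simplification, not hemodynamics.

This split of information has a deliberate consequence: PPG alone carries
the systolic coordinate, which separates all five classes (their systolic
sampling ranges are disjoint); ECG alone carries the diastolic coordinate,
under which normotension and prehypertension coincide — capping an ECG-only
classifier near 80% on balanced data. The concatenated model sees both and
approaches ceiling, reproducing the qualitative ordering
concat > PPG-only and concat > ECG-only.

**Default study conditions**: fs = 125 Hz, heart rate drawn per record from
55–95 bpm, beat-to-beat interval jitter ±3% available (0 by default per
record config), PPG/ECG additive white noise at 20 dB SNR, per-beat SBP/DBP
jitter uniform ±1.5 mmHg. Class targets are drawn from the interior of each
class box at least 2 mmHg from every boundary, so the bounded jitter can
never cross a class line; open table bounds get synthetic floors
(hypotension SBP ≥ 60, DBP ≥ 40; normotension SBP ≥ 90, DBP ≥ 60). SNR-scaled
noise is applied to PPG and ECG only; ABP noise is a separate absolute knob
(default 0 mmHg) because a 20 dB perturbation of a ~50 mmHg pulse would move
per-beat extrema across the 2 mmHg margins and break the ground truth.

What the generator does **not** emulate: arrhythmias, motion artifacts,
sensor saturation, baseline wander (an optional sinusoidal wander exists to
exercise the filters), patient-specific morphology, or any realistic
coupling between pressure and waveform beyond the monotone mappings above.
Passing the end-to-end tests therefore demonstrates that the pipeline and
model are implemented correctly and can learn class-informative morphology —
it does not certify clinical performance on real recordings.

## Benchmark problem sizes

The canned benchmark (`pulsestage.experiments`) uses 400 beats per class
(~2,000 segments), a 64/16/20 split, 5-fold CV, depth 5, batch 32, up to 40
epochs with patience 8 — sizes chosen so the full three-mode comparison runs
in minutes on one CPU while keeping per-fold variance small. At these
settings the concatenated model reaches ~0.95–0.99 mean fold test accuracy,
PPG-only ~0.95, ECG-only ~0.76, and the input-mode ANOVA p-value is far
below 0.05.

## Known limitations

- The numpy training loop is single-threaded and eager; it is sized for the
  benchmark scales above, not for hundreds of thousands of segments.
- Segment-wise splitting lets beats from one record appear on both sides of
  a split; use the carried `source_record` for subject-wise evaluation on
  real data.
- The WFDB support is a minimal single-`.dat`, format-16 reader/writer meant
  for round-trip testing and simple monitor exports, not a full
  implementation of the format family.
- Unclassifiable pressures are dropped, so extreme readings (SBP > 180,
  DBP > 120) are invisible to the classifier by design.
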