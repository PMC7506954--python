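# Methods

## The analysis

`carrygait` implements a subject-independent classification pipeline for
carrying gait. The experimental protocol it models has each participant
walk one laboratory crossing under each of 19 load conditions — no load,
a 30-lb frontal box (symmetric, 25/5 left-heavy, 5/25 right-heavy), and
fifteen dumbbell configurations over {5, 15, 25} lb per hand — while wearing
a full-body inertial motion-capture suit (66 joint-angle channels: 22 joints
× 3 planes at 240 Hz, plus heel-strike events) and two surface-EMG
electrodes over the left and right erector spinae (2148 Hz), with one
maximum-voluntary-contraction (MVC) reference per participant.

Processing stages:

1. **Step segmentation.** Heel-strike events delimit steps: a *right step*
   runs left heel strike → right heel strike and vice versa; windows are
   half-open so each sample belongs to exactly one step. Same-side
   consecutive events (imperfect detection) drop that pair with a warning.
2. **Inertial features.** Per step and channel: mean and variance of the
   raw angle and of its absolute value. Per-step values are averaged over
   all left steps and all right steps separately: 66 × 4 × 2 = 528 features
   per trial. Variance uses the sample (n−1) denominator.
3. **EMG features.** Linear detrend → 2nd-order Butterworth 20–450 Hz
   bandpass → rectification → 2nd-order Butterworth 10 Hz lowpass →
   division by the maximum of the participant's processed MVC envelope.
   Per muscle: envelope mean and RMS per step, averaged per step side
   (8 features), plus the median amplitude of peaks of the unsegmented
   normalized envelope with amplitude ≥ 10% MVC and duration ≥ 0.2 s
   (2 features). A lost sensor system zero-fills its features and sets a
   flag.
4. **Feature selection.** Sequential floating forward selection. A
   candidate's score is the partial-F p-value for adding it to an OLS model
   of the numeric class code on the already-selected features;
   F = (RSS₀−RSS₁)/(RSS₁/(n−q−2)) on (1, n−q−2) df. After each inclusion,
   selected features whose removal p-value exceeds the exclusion threshold
   are floated out (worst first, never the feature just added). If the
   final set exceeds 50 features the whole run repeats at a stricter
   threshold: 0.05 → 0.01 → 0.001.
5. **Classification.** Four classifiers on z-scored (training-fold
   statistics) selected features: LDA, linear SVM (C = 1, one-vs-one),
   a bagged ensemble of 100 decision trees (EDT), and multiple linear
   regression whose continuous output is rounded half-up to the nearest
   class code (REG). Evaluation is leave-participant-out cross-validation;
   the reported score is the mean over participants of the per-fold
   percentage of correctly classified trials.

Five problems are defined over the conditions: P1 box vs. no box (2
classes); P2 box vs. one dumbbell vs. two dumbbells (no-load skipped); and
three 3-class asymmetry problems over the non-box conditions — P3 splits
the left–right weight difference at 20 lb, P4 at 10 lb (symmetric / ≤10 /
>10), P5 classifies the heavier side. Classes are coded 1..K in listing
order; the no-load condition counts as symmetric. Note that enumerating
the protocol gives 9 two-dumbbell conditions, so P2's class sizes are
(3, 6, 9) per participant.

## Decisions where the design was open

* **Selection statistic.** The "p-value" criterion is realized as a partial
  F-test within an OLS on the numeric class code. This matches the REG
  classifier family and classical stepwise-regression practice, and makes
  the criterion scale-invariant. Candidates collinear with the selected
  block (relative rank tolerance 1e-10) score p = 1; ties break by
  canonical feature-name order, so selection is fully deterministic.
* **Selection scope.** The default selects once on the full dataset before
  cross-validation, reproducing a single per-problem feature count; this is
  optimistically biased, so a leakage-free per-fold mode is available
  (`selection_mode="per-fold"`).
* **Filtering.** All EMG filters run forward–backward (zero phase),
  standard for offline analysis; this doubles effective filter order.
  Detrending is linear, not mean-only. "Peak duration" is the width at
  half prominence (the common peak-width convention).
* **P4 boundary.** The asymmetry split is ≤10 lb vs >10 lb; with the
  realized asymmetries {0×4, 5×2, 10×4, 15×2, 20×2, 25×2} this is the only
  reading that yields balanced (4, 6, 6) classes.
* **Rounding.** REG predictions round half-up (`floor(x+0.5)`) and clip to
  [1, K]; the median of an even number of peaks is the midpoint of the two
  central values.

## The synthetic cohort

No recorded human data ship with the package; a seeded generator produces
cohorts whose statistical structure carries the effects the analysis is
meant to detect. Joint-angle channels are truncated-Fourier waveforms
(3 harmonics of the stride frequency, fixed per-channel phases, right side
in antiphase) gated to the walking span between the first and last heel
strike, with ~2 s of quiet standing on both ends; heel strikes alternate
sides every half stride with 2% timing jitter over 10–14 steps
(stride period ≈ 1.1 ± 0.06 s per participant). Participant random effects
(per-joint amplitude gains and baseline offsets, mirrored left/right; EMG
gain) make leave-participant-out generalization a real test.

Injected condition effects, with defaults chosen to be biomechanically
plausible and to reproduce the qualitative phenomenology the analysis
assumes:

| effect | default | meaning |
|---|---|---|
| `box_arm_posture_deg` | 60° | elbow-flexion offset (shoulder: half) for box carries |
| `box_armswing_residual` | 0.1 | arm-swing amplitude remaining during box carry |
| `armswing_suppression_per_lb` | 0.03/lb | same-side arm-swing reduction per pound held |
| `wrist_variability_suppression` | 0.02/lb | extra same-side wrist-channel reduction |
| `trunk_lean_deg_per_lb` | 0.15°/lb | lateral-bending offset per signed lb of (right−left) |
| `emg_load_gain_per_lb` | 0.012/lb | own-side erector spinae burst gain |
| `emg_contralateral_gain_per_lb` | 0.03/lb | opposite-side burst gain (dominant) |
| `emg_asymmetry_gain_per_lb` | 0.01/lb | bilateral stabilization gain on \|left−right\| |
| `kinematic_noise_deg` | 1.0° | white angle noise (≈ sensor dynamic accuracy) |
| `emg_noise_level` | 0.02 | additive broadband EMG noise |

EMG is a 20–450 Hz band-limited Gaussian carrier modulated by one Gaussian
burst per heel strike per muscle. The contralateral term dominating the
own-side term reproduces the observation that the erector spinae opposite a
unilateral load works harder. The bilateral `emg_asymmetry_gain_per_lb`
term models trunk co-contraction growing with load asymmetry; it exists
because a purely signed left–right EMG response is linearly uninformative
about asymmetry *magnitude*, whereas the study's EMG demonstrably improved
those problems — without some magnitude-responsive component the linear
selection/regression chain could not use EMG there at all. The MVC
recording is a 5 s plateau at twice the largest possible trial burst, so
normalized envelopes stay in [0, 1] up to noise.

What the generator does **not** emulate: real gait curve shapes (only
per-step moment structure matters downstream), ground-reaction dynamics,
IMU drift, electrode artifacts, handedness asymmetries, speed variation
within a trial. Passing tests therefore demonstrate that the pipeline
recovers effects of the assumed structure from noisy multichannel data with
participant-level heterogeneity — not that real-data accuracies would be
reproduced. On default cohorts the qualitative structure matches the
source study: the frontal-load problem is perfect (100%), carry-mode
classification is in the mid-90s, and asymmetry-level problems are far
harder, with EMG features lifting them when kinematic asymmetry cues are
weak.

## Numerical choices and degenerate inputs

* Zero-phase SOS filtering throughout; envelopes are clipped at 0 (the
  lowpass can undershoot slightly); EMG recordings shorter than ~0.9 s
  (3 × the 10 Hz filter's settling span) are rejected.
* Single-sample step windows return variance 0 with a warning; a trial
  side with no steps zero-fills that side's features with a warning.
* SFFS stops when the current model is numerically saturated
  (residual sum of squares ≤ 1e-12 of the response's total) and carries an
  action cap (10 × number of features) against add/remove cycling; a
  perfect candidate fit reports p = 0.
* Rank-deficient REG designs fall back to the minimum-norm least-squares
  solution with a warning.
* Floats are serialized with 10 significant digits; round-trips are exact
  to better than 1e-9 relative, and re-serializing an unmodified object is
  byte-identical.
* All randomness flows from one root `SeedSequence`; per-participant and
  per-trial streams are spawned in a documented, stable order, so equal
  seeds give byte-identical artifacts.

## Problem sizes used in tests

The test suite and the acceptance script run cohorts of 10 participants
(190 trials) for the headline experiments — the cohort size of the study
design — and 2–4 participants for structural and I/O checks. Property
checks compare the numeric kernels (step moments, OLS coefficients,
partial-F p-values, peak detection) against independent brute-force
oracles on 100 randomized instances each.

## Known limitations

* The pooled (pre-CV) selection mode leaks class information into the
  folds by design fidelity; use `per-fold` for unbiased estimates.
* The EDT classifier's trees and the SVM's one-vs-one reduction follow
  scikit-learn's implementations; "ensemble decision tree" is instantiated
  as bagging with 100 trees and a fixed seed.
* The 22-joint/3-plane channel vocabulary is a documented convention of
  this package reconstructed from the sensor system's biomechanical model;
  other deployments must map their channel names onto it.
* Effect sizes for the injected phenomena are not measured quantities;
  only their directions are grounded in the source observations.
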