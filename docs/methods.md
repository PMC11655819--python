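# Methods

## The problem

Averaged event-related potentials (ERPs) confound three sources of
trial-to-trial variability: latency **jitter** within a condition (which
smears and attenuates the average), latency **shifts** between conditions or
participants (which masquerade as amplitude effects and produce biphasic
difference waves), and genuine amplitude/topography differences.  The same
confound affects single-trial classifiers: a CNN trained to discriminate two
conditions cannot tell whether its accuracy comes from amplitude,
topography, or timing.  `erplat` implements a stepwise latency-correction
pipeline that removes these sources one at a time, and a classifier-based
assessment protocol that measures what each removal does to decoding
performance.

## The correction model

Each single trial is modeled as a sum of three component clusters plus
noise:

* **S** — stimulus-locked, fixed latency;
* **C** — central, cognition-related, with unknown per-trial latency;
* **R** — response-locked, latency given by the trial's reaction time.

**Step 1 (decomposition).** Residue iteration decomposition, run per
subject and condition: alternate between (a) re-estimating each component's
spatiotemporal template as the latency-locked pointwise average (median by
default, mean optional) of the residual after subtracting the other two
components, and (b) re-estimating each trial's C latency lag as the lag
maximizing the summed-over-channels covariance between the C residual and
the C template.  Iteration stops when the relative Frobenius change of all
templates falls below `tol = 1e-3` or after `max_iter = 10` iterations
(non-convergence is a warning, not an error — in practice the templates
plateau while the criterion is still ~1e-2).  Only the C components are
retained for the later stages.

Numerical choices:

* Search windows: S `[0, 300)` ms, C `[200, 900)` ms post-stimulus, R
  `[-300, 300)` ms around the response, anchored at the cell's median RT.
* The lag search range is ±200 ms, clipped so the shifted C window stays
  inside the epoch; ties break toward the smallest `|lag|`, then earlier.
* Before each lag scan, residual and template are smoothed with a 40-ms
  moving average — low-pass matched filtering that suppresses broadband
  noise without displacing component peaks (at a single-trial C-peak SNR of
  1 this raises latency-recovery correlation from ~0.57 to ~0.87).  Set
  `latency_smooth_ms=0` to disable.
* Templates carry raised-cosine edge ramps of 24 ms inside their window (a
  guard against subtraction edge artifacts).  A *fixed-duration* ramp is
  used rather than a fraction of the window: a 10%-of-window ramp on the
  700-ms C window would be 70 ms wide and would clip the flank of
  components near the window edge, leaving a systematic condition
  difference after synchronization.
* Templates are re-projected to the average reference after estimation (the
  pointwise median of average-referenced trials is not exactly channel
  zero-mean).
* With zero latency variability the decomposition is non-identifiable: a
  stationary C flank inside the S window is indistinguishable from S.  The
  method needs jitter to separate the streams; test scenarios include it.

**Step 2 (within-condition jitter).** Every trial is shifted by the
negative of its estimated lag (integer samples, zero-padded), aligning
trials to their template while preserving between-condition and
between-subject latency differences.

**Step 3 (between-condition shifts).** Per subject, each condition's peak
latency at the reference electrode (`Pz` by default, maximum `|v|` in the C
window) is measured on the post-Step2 condition average, refined to
sub-sample precision by parabolic interpolation; both conditions are
shifted uniformly toward the midpoint.  The two integer shifts are rounded
*jointly* — their difference equals the rounded peak gap — so the residual
misalignment never exceeds half a sample.  (Independent rounding can leave
a full-sample misalignment, a ~5% residual difference for a 120-ms-wide
component at 250 Hz.)  Shifts remain integer-sample throughout; the
remaining sub-sample phase difference between conditions is irreducible for
a single subject but averages out across participants in grand averages.

**Step 4 (between-subject shifts + amplitude normalization).** Each
subject's condition-common peak latency is shifted to the median across
subjects.  Then every trial is divided, time point by time point, by its
global field power (GFP = population standard deviation of voltage across
electrodes, `ddof = 0`), equating overall activation while preserving the
topography.  Time points with GFP below `eps = 1e-12` µV become zeros.
GFP normalization is per trial, requires average-referenced input (asserted
at `1e-6 · max|v|`, never re-applied), and is idempotent.

All stages are cropped to the analysis window `[100, 1100)` ms *after*
shifting, so zero padding stays outside what the classifiers see.  Windows
are half-open throughout: 1 s at 250 Hz is exactly 250 samples.
Millisecond-to-sample conversion rounds half away from zero.

## Classifier-based assessment

Two classifiers are applied to each stage's dataset:

* **Compact CNN** — temporal convolution band (`K1 = 4` kernels of length
  `L1`, same-padded), grouped spatial filters (`K2 = 2` per temporal map,
  spanning all `C` electrodes), depthwise-separable integration (length
  `L2 = L1/2` depthwise kernels, 1×1 pointwise merge), batch normalization
  after each convolution, ELU, average pooling (4 then 8 samples, clipped
  for short inputs), dropout 0.2 in blocks 2–3, single-logit sigmoid head.
  `L1` defaults to half the input length rounded down to odd.  Trained with
  Adam (lr 0.05, weight decay 1e-3, batch 64, 100 epochs, no early
  stopping); all randomness flows from one seed, so training is
  bit-reproducible.  The network, its backward passes and the optimizer are
  implemented directly on numpy; gradients are verified against numerical
  differentiation in the test suite.
* **Logistic baseline** — L2-regularized logistic regression on flattened,
  standardized voltages (scikit-learn).  It reproduces the same qualitative
  stage ordering as the CNN and is the default for speed.

Protocol: 10-fold cross-validation, trial-level and stratified by
condition, pooled across subjects (a subject's trials may appear in both
train and test — the pooled design; a subject-grouped split is available
via `grouped_by_subject=True`).  Significance versus chance 0.5 uses the
one-sample t-test across folds.  For permutation-null calibration the
corrected resampled t-test (variance inflated by the 1/(k−1) test/train
ratio) is provided, because the plain fold t-test is liberal under the null
(measured 3.3% false positives at nominal 1%).

**Temporal decoding** slides a 120-ms window in 4-ms steps across the
epoch (221 windows of 30 samples on the 1-s epoch) and runs the same CV
per window; points are labeled by the window endpoint.  **Temporal
generalization** trains on each window and tests on all windows with the
same folds, so its diagonal reproduces the temporal-decoding curve exactly.
Below-chance off-diagonal cells diagnose time-shifted, pattern-reversed
structure between conditions; they disappear after Step 3.

**Saliency maps** attribute a fitted CNN's logit to channels × time with
the DeepLIFT rescale rule against an all-zero baseline (the
average-referenced resting state); gradient × input is the fallback.  The
rescale implementation is complete (attributions sum to the logit
difference) and reduces exactly to gradient × input on linear models.
Condition maps average signed attributions of trials classified correctly
with probability above 0.9, per condition, then combine the two condition
means into one signed map.

## The synthetic-data generator

The simulator emulates the structure of a two-condition face repetition
priming session: per subject, 72 trials per condition, 41 electrodes
(10-10 montage including `Pz`), 250 Hz, epochs −100…1500 ms around target
onset.  Components: S (Gaussian, 150 ms, 80-ms FWHM, 4 µV), C (Gaussian,
120-ms FWHM, 5 µV at the peak electrode, mean latency 360 ms primed /
440 ms unprimed, 50-ms within-condition jitter, 30-ms between-subject
offset), R locked to the reaction time (100-ms FWHM, 3 µV);
RT = C latency + log-normal motor delay (σ = 0.2), so response timing
co-varies with the central process and condition RT medians differ, as
priming does behaviorally.  Topographies are smooth random zero-mean
channel weightings (the C topography peaks at `Pz`, matching the choice of
synchronization electrode); noise is channel-correlated Gaussian
(optionally white or 1/f-colored), 5 µV by default — single-trial C-peak
SNR ≈ 1 at the peak electrode.  Everything is projected exactly to the
average reference.  One seed determines the dataset bit-for-bit, with
per-subject sub-streams.

What the generator does **not** emulate: realistic volume-conduction
topographies, ocular/muscle artifacts, non-stationary noise, multiple
simultaneous C subcomponents, per-electrode latency differences.  Passing
tests therefore demonstrate the internal correctness and the qualitative
behavior of the method under its own model assumptions, not performance on
real recordings.

## Problem sizes used in tests and the acceptance script

Scenario sizes are chosen so each check's sampling error is small relative
to its tolerance: latency recovery uses one subject × 72 trials per
condition (the per-cell size of the emulated study); the jitter-smearing
check uses 800 trials in one condition so the realized-jitter error of the
smearing factor (~1%) sits well inside its 3% tolerance; the
phase-reversal check uses a 5-subject grand average (per-subject
sub-sample misalignment averages out); stage-ordering decoding uses 3
subjects × 72 trials × 2 conditions with the logistic baseline over 5
seeds; generalization probes use a 120-ms window with a 40-ms stride.
CNN-specific tests run on reduced geometry (≤ 8 channels, ≤ 50 samples)
where its training is fast and its gradients are numerically verifiable.

## Known limitations

* Integer-sample shifting leaves a sub-sample residual misalignment
  between conditions for any single subject (≤ 0.5 sample after coupled
  rounding, up to ~2% of peak for a 120-ms component at 250 Hz).
* The decomposition assigns stationary overlap ambiguously when a
  component has (near-)zero latency variability; S/C separation relies on
  jitter.
* A single C cluster is modeled; multiple concurrent latency-variable
  clusters are out of scope.
* Per-electrode latency corrections are not attempted (shifts are applied
  to all electrodes equally).
* The compact CNN is CPU-oriented and intended for the small geometries of
  the bundled tests and simulations, not for large-scale training runs.
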