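# Methods

This note records how `graphokin` defines its quantities, which parameters
matter, what the synthetic generator does and does not emulate, and the
design choices made where the problem was genuinely open.

## Data model

A recording is a time-ordered multichannel series: timestamp (s), pen
position x, y (device units; 0.25 mm/unit on the reference hardware, x along
the writing direction, y downward), tip pressure normalized to [0, 1], two
pen inclination angles in [−60°, 60°] (tilt-x along the written line, tilt-y
below it), and an on-surface flag. Hover samples are kept in the stream —
the in-air-time ratio needs them — and excluded from geometric and dynamic
features through the flag. Pressure calibration across tablet models is the
acquisition step's responsibility; the loader only enforces the [0, 1] range.
Irregular sampling is tolerated: every time computation uses actual
timestamps, and the nominal sampling rate (200 Hz default) enters only the
spectral frequency axes. A *stroke* is a maximal contiguous on-surface run;
words and text lines are groupings of strokes.

## Spectral engine

Every frequency-domain feature uses one pipeline: split the signal into
consecutive non-overlapping packets of `packet_size` samples (600 default;
trailing remainder discarded so all packets share one frequency axis),
remove each packet's mean, take squared rFFT magnitudes, average across
packets, normalize the averaged power to unit sum. Normalization discards
amplitude and keeps spectral *shape*, making writers with different writing
sizes and sensor gains comparable; it also makes every summary invariant
under signal scaling. A Hann-taper option exists but the default is the
rectangular window, matching the plain description of the procedure.

Summaries of a unit-sum spectrum P(f):

* **median** — the smallest f with cumulative power ≥ ½;
* **bandwidth at coverage c** (0.90 default) — Q(1−α) − Q(α) with
  α = (1−c)/2 and Q the same discrete left-continuous quantile. "The range
  covering 90% of the density" admits several readings (smallest covering
  interval, [0, 90th percentile]); symmetric tails were chosen because they
  are unique, monotone in spread, and give 0 for a single-line spectrum;
* **distance to reference** — Euclidean distance between unit-sum power
  vectors on an identical axis. No resampling is done; mismatched axes are
  an error, by design, because interpolated power vectors would not sum to 1.

Whether per-packet spectra should be normalized before averaging was open;
normalizing *after* averaging was chosen so that packets with more power
(more activity) weigh proportionally.

**Short recordings.** A 600-sample packet needs ~30 s of on-surface writing
for the subsampled derivative series, so truncation experiments (15 s)
would lose all spectral families. The packet therefore shrinks adaptively to
the largest power of two that fits the series, with a floor of 128 samples;
below that the family is reported missing. To keep distances well defined
across writers, a cohort extraction fixes one packet size per family — the
smallest adaptive size any cohort member supports, capped at the configured
600 — and the cohort reference stores that axis; single-recording extraction
against a reference adopts the reference's packet size.

## Tremor signal

Within consecutive windows of 10 on-surface points (never straddling a
stroke boundary; remainder points at stroke ends are skipped), the 9
difference vectors **d**ᵢ between consecutive points are compared with
their window mean **ḡ**; each emitted value is |**d**ᵢ × **ḡ**| (z-component
magnitude). The construction is translation- and rotation-invariant and
zero for collinear motion; sideways jitter scales it linearly. The emitted
series (9 values per 10 raw points) feeds the spectral engine at the
recording's nominal rate; packet accounting is done on emitted values.

One caveat discovered during validation: because the cross product is a
*rectified* bilinear form, injecting a pure positional tremor at 8 Hz does
**not** place the tremor-spectrum median at 8 Hz — power lands at
rectification harmonics, and the median saturates near 22 Hz independent of
amplitude. What does hold, and what the tests assert, is that the mean
tremor signal and the tremor bandwidth increase strictly with injected
amplitude, and that smooth traces have narrower tremor spectra than shaky
ones.

## Derivative features

All dynamic channels share one smoothed-derivative engine, applied per
stroke: moving average with window n = 10 raw samples, retain every 10th
smoothed point, derivative between consecutive retained points using actual
timestamps. Because the engine runs within strokes, no measurement spans a
pen lift. Speed is ‖Δ(x, y)‖/Δt; channel-change speeds are |Δc|/Δt for
pressure (1/s) and each tilt angle (deg/s) — the magnitude form is used
because the features are speeds and their units demand value-over-time.
Summary statistics use the population (not sample) standard deviation.
"Evolution over time" features are ordinary least-squares slopes of the
series against time. The extrema rate applies a Gaussian filter whose width
is specified in *seconds* (0.25 s default — wide enough to suppress sensor
noise, narrow enough to keep saccades) so results survive resampling, then
counts strict local maxima plus minima and divides by the recording's
on-surface duration (off-surface time would inflate the denominator without
adding writing). The in-air ratio attributes each inter-sample interval to
its left sample's state and uses exact (fsum) summation, so it equals a
brute-force timestamp sum identically.

## Feature vector

52 named scalars in a fixed order: 8 static, 12 kinematic, 10 pressure,
22 tilt (the four-family inventory enumerates to 52; the count is fixed by
the named list in `graphokin.dynamics_features.FEATURE_NAMES`, with
extension points for additional features). Features a recording cannot
support are NaN — flagged, never imputed. Word segmentation (needed for
spacing) merges consecutive strokes unless a pen-up longer than 0.15 s
*and* a horizontal box gap wider than 40 units separate them; line
segmentation starts a new line when a stroke's x-start retreats by more
than half the running line width while its y-centroid drops by more than
the running median stroke height. Both algorithms, and their thresholds,
are this package's own (no published procedure exists for them) and are
exposed in the configuration. The word-spacing feature is ln(mean gap) — 
the log transform tames the right-skewed gap distribution — plus the raw
standard deviation of gaps, which captures spacing irregularity.

## Evaluation protocol

The protocol description combines a fixed 70/30 per-class split with
"k-fold cross-validation, k = 25" — incompatible readings; since a mean and
standard deviation over repeats are reported, it is implemented as k = 25
independent *stratified shuffle splits* with 70% of each class training
(plain stratified k-fold remains available via `CVConfig(mode="kfold")`).
Per repeat a 100-tree Random Forest (unlimited depth, √p features per
split, seeded) is fit; reported are per-repeat F1 with the dysgraphic class
positive (F1 = 2·P·R/(P+R), precision 0 when nothing is predicted
positive), sensitivity, specificity, false-positive rate, and normalized
Gini importances. No class weighting or resampling is applied to the
imbalanced cohort, mirroring the reference protocol. Rows with missing
required features are dropped per evaluation with a logged count; columns
missing for *every* row (spectral families on very short truncations) are
dropped first so a short-duration evaluation does not discard the cohort.

**Reference hygiene.** Distance-to-mean features depend on a cohort
reference spectrum. Extraction therefore returns per-recording family
spectra alongside the feature table, and each evaluation repeat rebuilds
the reference — and the five distance columns — from its training split
only. Trained models store their reference, and refuse feature vectors
whose names or completeness do not match.

The no-information baseline used in permutation checks is the
majority-class (prior) predictor: under label permutation a forest on an
imbalanced cohort converges to predicting the majority class, whose F1 for
the minority-positive class is 0.

## Synthetic generator

The generator is a *test harness*, not a model of children's handwriting.
Within a word the pen advances along an arc-length-parameterized chain of
oscillatory letter loops (width 110, height 44 units; the inverse arc-length
parameterization makes the pen's measured speed equal its nominal speed
rather than an artifact of loop curvature — with sharper loops, smoothing
chord-shortening would alias letter geometry into the speed spectrum).
Nominal speed is base_speed·exp(s(t)) with s a piecewise-constant log-factor
jumping at a Poisson rate (abrupt multiplicative saccades). Narrowband
tremor (phase-diffused sinusoid, 8 Hz default) is added to both
coordinates. Word gaps are Gaussian; each pen lift inserts an in-air hop
whose duration realizes the profile's target in-air fraction; lines break
after a fixed word count. Pressure is a clipped mean-reverting AR(1)
process; each tilt angle is a base value plus a phase-diffused sinusoid
plus optional broadband jitter. Exactly ⌈duration·rate⌉ samples are
produced; a (profile, seed) pair is byte-reproducible, and cohort writers
draw per-writer parameters (7% lognormal jitter) from independently spawned
streams, so enlarging a cohort never perturbs existing writers.

Default group profiles differ in the directions documented for real
cohorts — the dysgraphic profile has more tremor (2.0 vs 0.4 units), more
and larger speed saccades (4/s, 0.5 vs 1.5/s, 0.2), slower base speed (240
vs 320 units/s), smaller and more irregular word gaps (80 ± 40 vs 140 ± 25
units), more in-air time (0.28 vs 0.18), slower tilt-y modulation (1.2 vs
3.0 Hz), broadband tilt-x jitter (3.0 vs 0.5°) and livelier pressure
dynamics — at ≈2 pooled SD per manipulated knob, so classification tests
are stable at desk scale; a "hard" preset shrinks the differences to ≈0.5
SD. What the simulator does **not** emulate: real letterforms or any
language, letter-level shape variability, fatigue and learning effects
within a session, device noise characteristics, or pediatric motor-control
dynamics. Passing tests therefore demonstrate that the pipeline measures
what it claims and that the protocol recovers planted structure — not that
the classifier's synthetic accuracy transfers to clinical recordings, whose
headline numbers are expressly out of scope here because that data cannot
be redistributed.

## Problem sizes and numerics

The validation suite and the acceptance script use: 100 random signals for
the DFT-oracle check (tolerance 1e−9 relative; observed ~1e−14), 40 + 40
writers at full study conditions (300 s, 200 Hz) for direction recovery and
the 15-s/300-s robustness comparison, and the study-sized 242 + 56 cohort
for the k = 25 protocol, permutation null, and importance ranking. Because
importance spreads across the many co-separating features of 52, "planted
features surface" is asserted as: at least three of the six
contrast-matched feature families place a member in the Gini top 10 (the
exact count varies by two or so across cohort seeds; the acceptance script
reports it as a number rather than a pass/fail). Unit-sum
normalization is checked to 1e−9; degenerate inputs (constant signals,
empty strokes, single-class cohorts, all-missing vectors) raise typed
errors rather than producing silent NaNs, except where the contract says
"missing, not fatal".
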