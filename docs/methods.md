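# Methods

This note documents the models, numerical choices and limitations of the
`aquamyo` pipeline: what each stage computes, why its defaults are what
they are, and what the synthetic cohort does and does not emulate.

## Synthetic cohort model

The generator exists because raw subject recordings for this study
design are not publicly deposited; it produces cohorts with the
statistical structure the downstream analysis assumes, so every stage is
testable end to end.

**sEMG carrier.** Band-limited Gaussian noise: white Gaussian noise is
multiplied in the frequency domain by a Gaussian *amplitude* profile
`exp(−(f−f_c)²/(4σ_f²))`, giving a Gaussian *power* spectrum with center
`f_c` (default 80 Hz) and scale `σ_f` (default 25 Hz), then normalized
to unit RMS.  This was chosen over autoregressive shaping because the
mean and median frequency of the output are then directly controllable:
for `f_c = 80`, `σ_f = 25` the sub-zero spectral tail is 3.2σ away and
shifts MNF by under 0.1 Hz, and band-limiting features to 20–450 Hz
shifts it by about +0.6 Hz — well inside the ±3 Hz recovery tolerance
the tests check.

**Envelope and timeline.** Each trial is a rest stage (default 30 s, a
shortened stand-in for the protocol's 5-minute baseline; configurable)
followed by a 30 s isotonic contraction stage divided into equal slots,
one per repetition.  Activation occupies 70% of each slot with a
trapezoidal envelope (10% rise/fall of the active window); the plateau
RMS equals the requested amplitude.  An optional linear fatigue decay
(default 5% across a set) lowers successive repetitions, reproducing the
reported downward trend of time-domain features over repetitions; the
study reports the trend but no rate, so the rate is a package default.
Repetition duration and inter-repetition pause are not specified in the
source protocol; the 70% duty default fits the stated 30 s contraction
windows at all three repetition counts.

**Movement pulses.** Each repetition's acceleration is a rotating vector
in the x–y plane with magnitude `p·sin(πt/L)` and direction sweeping
0→π over the movement, so each axis is biphasic (flexion then extension)
while the gravity-removed magnitude has a single hump — one detectable
event per repetition.  A 100 ms half-sine jerk transient at half the
pulse peak marks movement initiation, as abrupt load changes do in real
limb movement; without it, the slow sinusoidal rise of a 3-repetition
trial crosses a baseline-relative threshold tens of milliseconds late.
Gravity is a constant 1 g on the z axis (real devices vary in
orientation; configurable).  Matched angular-rate pulses use the same
shape.  Pulse peaks per repetition class (3.1/3.9/8.7 g, 48/110/213 °/s
before the ~0.446 duty-cycle factor) were set so segment-mean mACC/mGYR
land near the published per-condition levels (≈1.4/1.75/3.9 g and
≈21/49/95 °/s), with tricep kickbacks 10% more vigorous and aquatic
movement scaled by 0.95, both as printed.

**Class and environment effects.** Per (protocol, reps) activation
fractions mirror the published RMS levels (BC 0.41/0.36/0.33, TK
0.33/0.29/0.27 of MVC); spectral centers shift +12/+20 Hz with
repetition count and −8 Hz for tricep kickbacks, following the printed
mean/median frequency patterns.  Aquatic recordings are amplified by
1 + gain (default gain 0.15, comfortably above the reported ≥6%
intensification) and spectrally shifted +20 Hz.

**Variance components.** Each subject carries an amplitude factor
(relative submaximal activation, shared across environments and
protocols — this is what makes land and aquatic measurements of a
subject correlated, as the ICC assumes), a spectral offset, and an MVC
amplitude.  Defaults are anchored to the published dispersions: the
between-subject amplitude SD (0.05) matches the printed per-cell
SD/mean of ≈3–5% for time-domain features, and the within-subject
per-recording SD (0.03) reproduces the reported intra-subject CV% range
(2.7–6.4%) — the pipeline measures 2.7–6.0% on the default cohort.
Analytically these give a consistency ICC of
σ_b²/(σ_b² + σ_w²/m) ≈ 0.95–0.98 for per-environment cell means over
m = 15 recordings, matching the reported 0.93–0.98 band.  Subject and
trial spectral SDs default to 1.0/1.5 Hz so the 8 Hz protocol spectral
gap stays decisive for clustering.

**Seeding.** One master seed; every subject profile and trial stream is
derived by counter-based `SeedSequence` key splitting, so cohorts are
bit-identical across runs and any trial can be materialized
independently (cohorts are generated lazily — a full default cohort of
900 one-minute 7-channel recordings never resides in memory).

**What the generator does not emulate.** Motor-unit physiology,
electrode–skin impedance, water-infiltration artifacts, mains
interference, non-Gaussian or non-stationary noise, orientation drift of
the device, and realistic inter-subject spectral variability (real
cohorts show mean-frequency SDs of ~10 Hz and more across subjects; the
generator's 1 Hz default keeps exercise classes spectrally separable).
Consequently, passing tests demonstrate that the *pipeline* recovers the
structure it is designed for; they do not demonstrate that real aquatic
recordings have that structure.

## Preprocessing

sEMG: 4th-order Butterworth band-pass 20–450 Hz, zero-phase
(forward–backward second-order sections), the conventional surface-EMG
band; the source protocol states no cutoffs.  MVC normalization divides
by a per-subject reference; the pipeline filters first and normalizes
second (the order is unstated in the protocol; it only matters if the
reference was measured in a different band).  The MVC reference is the
maximum 500 ms rectified-RMS window of a designated MVC trial, computed
over fully covered windows only — as a max-of-estimates it carries a
modest (~10%) upward bias on stationary signals.  Envelope: 100 ms RMS
windows at 10 ms hop, truncated at boundaries rather than padded.

Accelerometer: a 0.3–15 Hz band-pass is provided (it removes
gravitational DC and high-frequency noise), but the default gravity
removal subtracts the rest-stage per-axis mean instead: the slowest
movement lobes of 3-repetition trials have ~0.15–0.5 Hz fundamentals
that a 0.3 Hz high-pass would visibly distort.  The band-pass remains
selectable (`preprocessing.gravity_removal: bandpass`) for recordings
without a usable rest stage.

## Segmentation

Threshold = rest-stage mean + k·SD (k = 3) of the gravity-removed
acceleration magnitude.  Sub-threshold gaps under 20 ms are bridged, but
only when the preceding supra-threshold run is itself substantial —
bridging from an isolated noise blip would drag onsets early.
Supra-threshold runs must last ≥100 ms; accepted onsets must be ≥250 ms
apart.  Following the device's acquisition rule, each activity window
runs from one onset to the next, the last closing at the signal end; a
conventional onset/offset mode is available behind `mode=
"onset_offset"`.  Adding a constant to the signal and its baseline
leaves detections unchanged (the threshold is baseline-relative), and
raising k never adds onsets.

## Features

Canonical definitions are implemented where the source table's typeset
formulas dropped absolute-value and squaring notation (IEMG printed as
`Σx_i`, SSI as `Σx_i`, mACC without the square root): `Σ|x_i|`, `Σx_i²`,
`√(x²+y²+z²)`.  Three deliberate literal readings: AAC keeps the printed
1/N prefactor over its N−1 terms (not 1/(N−1)); VAR divides the raw
energy by N−1 with no mean subtraction (sEMG is zero-mean after
band-passing); mACC/mGYR are segment *means* of the magnitude (a peak
statistic is selectable).  Spectra are Welch estimates (256 ms Hann
windows, 50% overlap); frequency features are computed on the 20–450 Hz
band in the pipeline.  MDF treats each bin's mass as sitting at the bin
center and interpolates linearly inside the crossing bin, so a single
spectral line yields exactly its own frequency; PKF breaks ties toward
the lowest frequency.  Features are computed per activity segment and
averaged per trial; statistics then aggregate trials.

## Statistics

The land-vs-aquatic test is the conventional two-sample t-test (H0:
equal means), Welch by default since equal variances across environments
is not a safe assumption; the source text inverts the hypothesis labels,
which is documented rather than imitated.  The one-way F-test
(between-/within-group mean square, df k−1 and N−k) complements it; for
two equal-variance groups F = t² exactly, which the tests verify to
1e-9.

ICC is computed from the two-way ANOVA mean squares; `icc()` defaults to
absolute agreement ICC(A,1) with one-way ICC(1,1) and consistency
ICC(C,1) selectable (verified against `pingouin.intraclass_corr`).  The
environment report uses the consistency form by default: the question it
answers is whether aquatic measurements *follow* the on-land ones
subject by subject, while the systematic aquatic intensification is
reported separately by the group means and the t-test; absolute
agreement would fold that intensification into unreliability (for
squared-scale features the 15% amplitude gain becomes a 32% offset and
dominates).

CV% is intra-subject *precision*: SD/mean × 100 across repeated sets of
one (subject, environment, repetition-class) condition, averaged over
conditions.  Computing it across environments instead would measure the
aquatic offset, not precision — for squared features the offset alone
contributes ≈20%.  The aggregation level (per subject, then averaged) is
a package decision; the source does not state one.

No multiple-testing correction is applied, matching per-feature p-value
reporting; a Benjamini–Hochberg adjustment can be applied downstream.
The reported ICC (0.92–0.98) and CV% (2.7–6.4%) ranges of the original
cohort depend on undeposited raw data; the package's property checks
(ICC > 0.8, CV% < 15% on the default synthetic cohort, ICC parameter
recovery within ±0.05 at n = 200) stand in for them.

## Clustering

k-means (scikit-learn, 10 restarts, fixed seed) on z-scored feature
columns; k defaults to 6, the number of protocol × repetition classes.
The clustering method, k and the scaling rule are package decisions —
the source presents clusters without naming any of the three.  By
default clustering runs within one environment (land).  On the default
cohort, combined sEMG+IMU features recover the 6 classes with ARI ≳ 0.85
while mACC+mGYR alone reach only ≈0.57: the IMU separates repetition
counts but confuses the two protocols, whose movement vigor differs by
only ~10%, whereas the sEMG amplitude and spectral gaps separate them —
the division of labor the multimodal design is meant to show.  The 9-rep
centroids carry the largest mACC/mGYR coordinates, the maximum being the
tricep-kickback 9-rep class, whose printed motion magnitudes exceed the
bicep-curl ones.

## Problem sizes and determinism

The default verification cohort is 15 subjects × 2 protocols × 2
environments × {3,6,9} reps × 5 sets = 900 recordings of 60 s at 1 kHz,
processed in a streaming pass (~25 s single-threaded).  Spectral
recovery uses 50 independent 60 s bursts; ICC recovery uses 200-subject
two-condition tables at true ICC 0.5/0.7/0.9.  All randomness flows from
explicit seeds; identical seeds give bit-identical cohorts, filter
outputs, and cluster assignments.

## Known limitations

- The printed results table is reproduced verbatim, including its
  internal duplications (PKF block identical to MDF; identical IMU rows
  across arms); the loader flags these rather than resolving them.
- The generator's realism limits are listed above; in particular the
  clustering result should be read as a pipeline property, not a claim
  about real aquatic data.
- Degenerate inputs are rejected rather than repaired: missing ICC
  cells are not imputed, all-zero spectra raise, zero-variance feature
  columns are dropped from clustering with a warning.
- EDF export is not implemented; the CSV + JSON-sidecar format is the
  canonical interchange, chosen for inspectability and exact (repr
  round-trip) numeric fidelity.
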