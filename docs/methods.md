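# Methods

`quieteye` reimplements, as a tested pipeline, the analysis chain that links
eye behaviour during a wall-throwing task to attention-test performance in
children: raw gaze streams and kinematic annotations are reduced to four
participant-level eye variables, two standardised instruments are scored
from raw response records, and the two variable sets are related through
correlations, shared variance, and canonical correlation analysis with
permutation inference.  Because the original participant data are available
only on request, a synthetic cohort generator with a planted cross-domain
dependence provides end-to-end recovery tests.

## Gaze geometry and fixation detection

Gaze is expressed in scene-camera degrees: a head-fixed frame, origin at the
image centre, x rightward, y upward.  The pixel→degree map is linear
(constant deg/px per axis: 60°/1280 px horizontally, 46°/960 px vertically
for the default camera), not tangent-corrected; at the ≤30° eccentricities
of a wall-target task the linearisation error is well below the 0.5°
nominal accuracy of the instrument, and the choice is isolated in
`pixels_to_degrees`.

Fixations are detected with the classic dispersion-threshold algorithm
(I-DT), since the vendor algorithm used in the original recordings is
undisclosed.  A window of consecutive valid samples grows while its
dispersion `max(range_x, range_y)` stays within the threshold (default 1.0°,
matching the quiet-eye spatial criterion) and is emitted as a fixation when
its wall-clock span reaches the minimum duration (default 100 ms).  Runs of
invalid samples up to a 75 ms gap tolerance are bridged inside a window —
bridged samples are excluded from the centroid but the duration keeps the
wall-clock span; longer gaps terminate the window.  Fixation boundaries are
the first and last valid member samples.  The greedy maximal-window variant
is used: from each start the window is extended as far as the threshold
allows, emitted if long enough, else the start advances one sample.  An
exhaustive brute-force implementation cross-checks this in the test suite.
At 60 Hz, one inter-sample interval (16.7 ms) bounds the timing resolution
of every event boundary; microsaccades are not resolvable and are not
modelled.

Trial reliability uses two ratios: the tracking ratio (valid samples /
total samples, threshold 0.85) and the fixation ratio (time covered by
fixations / trace span, threshold 0.60).  Both definitions are stated
explicitly because the original operationalisation is not public; the
denominators are configurable.

## Event synchronisation and the pre-throw window

The eye tracker and the external arm camera are synchronised through a
single optical flash visible to both; the model is one constant offset per
recording (external minus eye clock), with no drift term — adequate over a
few-second trial, and the residual error is bounded by one external-camera
frame (20 ms at 50 Hz).  Movement initiation (first frame of elbow-angle
increase) and ball release (first frame with the ball off the hand) arrive
as annotations on the external clock and are mapped to the eye clock before
analysis.  The analysis window is the 2000 ms interval ending at ball
release, half-open `[release − 2000, release)` to avoid double counting at
boundaries.

## Quiet-eye metrics

The quiet-eye (QE) fixation is the last fixation whose centroid lies within
1° (Euclidean) of the virtual wall target — the annotated ball-rebound
location — and whose onset strictly precedes movement initiation.  A
fixation starting exactly at initiation is rejected (strict reading of
"before").  Reported per trial:

* **QE onset** — initiation minus QE fixation onset; positive lead in ms.
* **QE duration** — the full fixation duration, not truncated at
  initiation: QE conventionally extends past movement onset, and observed
  duration maxima exceed typical onset-to-initiation spans.
* **fixation count** and **total fixation time (TT)** — over fixations
  overlapping the window, clipped to the window bounds, so TT ≤ 2000 ms by
  construction.

Participant-level metrics are arithmetic means over reliable trials; QE
means skip trials without a QE fixation rather than imputing zero, because
a zero would conflate "never fixated the target" with "fixated briefly".
Participants with fewer than 5 reliable trials (of 10) are excluded — a
majority-of-trials default, configurable, since the original study excludes
participants for poor data without stating a per-participant minimum.

## Attention instruments

**d2-R.**  The sheet is 14 rows × 57 characters (letters d/p with 1–4
dashes; target = d with two dashes); rows 1 and 14 are excluded from
scoring and rows 2–13 of the standard sheet hold 308 targets and 376
distractors; each row is worked 20 s (280 s total).  The bundled sheet is a
synthetic arrangement with exactly this structure (the real instrument is
copyrighted); it is generated deterministically in code.  Scores:
`CP = correctly marked targets − commissions` and
`%errors = 100·(commissions + omissions)/processed targets`, where the
processed span of a row ends at the rightmost mark or an explicit progress
marker.  The phrase "processed targets minus commission errors" admits a
literal reading that skips the "correctly marked" restriction; the standard
scoring is the default and the literal variant sits behind
`score_d2(..., literal_cp=True)`.  Raw scores map to standard scores
through an age-banded norm table; real d2-R norms are proprietary, so a
surrogate linear table (anchored to the cohort-level SS means/SDs of the
modelled study) ships with the generator, and any table in the documented
CSV layout can be dropped in.

**RTA.**  Only the 28 non-signal simple-reaction trials are scored (the
acoustic-warning set measures phasic, not tonic, alertness).  A correct
response lies in [100, 1000] ms — the 100 ms anticipation cutoff is a
standard RT-hygiene rule, configurable, not part of the original
description.  RT mean and SD use correct responses only with the sample SD
(n−1); `CVRT = 100·SDRT/RT`.  Note that a cohort-mean CVRT is *not* the
ratio of cohort-mean SDRT to cohort-mean RT — CVRT is computed per
participant and then averaged.

## Linkage statistics

Descriptives report the five-number summary, the adjusted Fisher–Pearson
skewness and the Shapiro–Wilk p-value.  Pearson correlations carry the
exact t-reference (`t = r√(n−2)/√(1−r²)`, df = n−2).  Shared variance is
the R² of one attention variable on the four-column eye block with its
F-test; individual regression coefficients are deliberately not exposed
because the eye variables are strongly intercorrelated and the coefficients
would be unstable while R² is not.  No multiple-testing adjustment is
applied across the correlation table (matching the reporting style being
reproduced).  Missing data: pairwise deletion for single correlations,
listwise for the multivariate analyses.

**Bootstrap double check.**  `bootstrap_p` tests independence with a
null-enforcing nonparametric bootstrap: x and y are resampled with
replacement independently of each other, which enforces the null while
preserving each margin, and `p = (#{|r*| ≥ |r̂|} + 1)/(B + 1)`.  The more
common percentile pairs bootstrap (p from the share of resampled r beyond
zero) was evaluated and rejected: at n ≈ 57 its type-I error is ≈ 0.067 at
a nominal 0.05 (BCa ≈ 0.062, studentized ≈ 0.061, measured at 10 000
Monte-Carlo replicates), whereas the null-enforcing scheme measures 0.049.
A double check should itself be calibrated; the choice and the measurements
are the package's own.

**CCA.**  Columns are standardised internally; the canonical correlations
are the singular values of `Qx.T Qy` from reduced QR factorisations of the
centred blocks — numerically stable under the strong within-set
correlations this data exhibits.  An explicit eigen-solution of
`Σxx⁻¹ Σxy Σyy⁻¹ Σyx` serves as the independent oracle in the tests.
Loadings are correlations of each observed variable with its own set's
variates; since canonical signs are arbitrary, each variate pair is
oriented so its largest-magnitude loading is positive (published loadings
may differ by a global per-variate flip).  An ill-conditioned within-set
covariance (condition number > 1e8) raises rather than silently
regularising.  Sequential Wilks statistics `Λ_k = Π_{i>k}(1 − ρ_i²)` get
permutation p-values by re-running the CCA on B row-permutations of one
set (whole rows, preserving within-set structure):
`p_k = (#{Λ_k* ≤ Λ_k} + 1)/(B + 1)`.  Permutation and bootstrap draws are
generator-seeded and bitwise reproducible.

## Synthetic cohort generator

The generator emulates the study conditions: 57 participants, 10 test
throws each, a 60 Hz gaze stream, the 2000 ms pre-release window, the full
d2-R sheet and the 28-trial RTA set.  A single participant-level latent
factor `G` (slow/error-prone direction) couples domains; all marginal
means/SDs are anchored to the participant-level descriptives of the
modelled study (QE onset 474 ± 227 ms, QE duration 754 ± 289 ms, 3.95 ±
1.10 fixations, RT 357 ± 54 ms, SDRT 56 ± 19 ms, SS centre/scale
90/11 and 90/10).

Traces are alternating fixations (gamma-distributed durations, shape 2;
within-fixation Gaussian jitter SD 0.15°) and 50 ms saccade gaps with
jumps of 4.5–9°, occasional 100–250 ms blink segments of invalid samples
(probability 0.10 per transition) plus 1.5% isolated dropouts; one
target-anchored fixation is planted with its onset preceding movement
initiation by the participant's QE-onset draw.  Trial-level QE variation is
multiplicative log-normal (CV 0.17 for onset, 0.15 for duration), keeping
draws positive without truncation; initiation sits ≈600 ms before release.
Saccade samples are placed in the interior band (30–70%) of the jump so a
detector sample can never be absorbed into a flanking fixation, and planted
fixation boundaries are recorded at the realised sample grid — together
these make noise-free recovery exact rather than merely within tolerance.
Default noise rates were fixed so that a default cohort loses no
participant to the 0.85/0.60 reliability rule (a design condition of the
emulated setting, where data-quality exclusions happen before the analysed
sample is formed).

**Planted dependence.**  `r_target` (default −0.417) is defined as the
population correlation between the *measured* participant-level QE onset
and the %errors standard score — the quantity the pipeline estimates — not
between latent propensities.  Averaging 10 noisy trials and binomially
marking a finite sheet attenuate any latent correlation, so the generator
disattenuates: it simulates a large fixed-seed reference population through
its own score-level noise model and root-finds (common random numbers,
Brent) the latent coupling whose implied measured correlation equals
`r_target`; the same reference population anchors the surrogate norm
tables.  This is the classical-test-theory correction, computed rather than
assumed.  Residual attenuation from effects outside the score-level model —
occasional jitter-induced fixation splits and trial exclusions — was
measured at about 0.02–0.03 at design time (mean recovered r ≈ −0.39
against a planted −0.417), within the ±0.05 recovery tolerance the tests
assert.

What the generator does *not* emulate: smooth pursuit of the ball,
saccade main-sequence kinematics, pupil dynamics, practice effects, age
trends, or any drift between the two camera clocks.  Passing recovery
tests therefore show that the *pipeline* is faithful, not that the
generator is physiologically realistic.

## Problem sizes used in the checks

The recovery experiments use 200 cohorts (57 × 10 trials) for the planted
condition and 100 for the null; inference calibration uses 2000 Monte-Carlo
replicates at B = 999; the detector and CCA oracles run on 1000 random
traces (≤200 samples) and 500 random 4×6-variable instances.  These sizes
put Monte-Carlo error well inside each asserted tolerance (e.g. the
SE of the 200-cohort mean correlation is ≈ 0.008 against a ±0.05 band).

## Known limitations

* The I-DT parameters are not claimed to match the undisclosed vendor
  detector; all thresholds are configurable.
* The surrogate norm tables standardise against the generator's reference
  population; absolute SS values are only meaningful relative to it.
* The single-offset synchronisation model ignores clock drift.
* The permutation test permutes one whole set's rows; it tests set-level
  independence, not conditional structure.
* With `literal_cp=True` the CP score ignores omissions entirely; the
  default follows standard d2-R practice.
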