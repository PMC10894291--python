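# Methods

This note documents the models, estimators, parameter choices and known
limitations of `gmamove`.

## Angle representation

Each joint is represented by the cosine similarity of the two limb-segment
vectors rooted at its anchor keypoint. The eight canonical anchors pair each
anchor with its anatomically adjacent keypoints: elbow → (shoulder, wrist),
knee → (hip, ankle), shoulder → (elbow, hip), hip → (knee, shoulder), per
side. The shoulder and hip endpoint pairs follow anatomical adjacency by the
same pattern as the elbow; they are isolated in `canonical_anchors()` so a
different convention is a one-line change.

Cosine similarity is invariant to translation, rotation and uniform scaling
of the image coordinates, so the angle series are camera-placement
insensitive up to perspective effects. Values are clamped to [−1, 1] after
floating-point evaluation so downstream range invariants hold exactly.

**Missing data.** A frame's angle is missing when any of the three keypoints
falls below a confidence threshold (default 0.0, i.e. only never-detected
points are masked) or when two keypoints coincide (zero-length vector).
Interior missing runs of at most `max_gap_frames` (default 5 frames ≈ 170 ms
at 30 fps) are linearly interpolated; longer runs and runs touching either
end stay missing. The defaults are deliberate guesses — dropped detections
are not characterized in NICU pose data — and both paths are exercised by
the synthetic generator's tests.

## Autocorrelation estimator

The normalized sample autocorrelation uses the standard estimator: full-series
mean, numerator over t = 1…T−k, denominator the full sum of squared
deviations. This guarantees r(0) = 1 exactly and |r(k)| ≤ 1 by
Cauchy–Schwarz. With missing values, the mean and denominator run over all
non-missing observations and the numerator over lag-k pairs with both
members present; the bound still holds because the numerator's
Cauchy–Schwarz factors are sums over subsets of the denominator's index set.
The estimator requires at least k+2 non-missing observations and a
non-constant series (zero variance raises a degenerate-series error).

Lags are specified in seconds and converted to frames by rounding half away
from zero at the sequence's frame rate; the frame rate is carried on each
series rather than hard-coded to 30 fps. r(k) is computed on the full
series, not on windows. The implementation is vectorized and is verified
against an independent brute-force double-loop oracle to 1e−12 in the tests.

## Group comparison

Per (joint, lag) cell, an independent two-sample t-test compares cohorts,
pooled-variance Student by default with df = n₁+n₂−2; Welch is available by
flag. Pooled is the default because every published (t, p) pair in the
reference grid is consistent with a pooled df = 8 test at the printed
precision (52 of 56 pairs round-match exactly; the rest differ by one unit
in the last printed digit, consistent with p computed from an unrounded t).
The signed t is first group minus second (default order: normal, CS), so
negative t means higher autocorrelation in the CS group. Zero pooled
variance with unequal means yields an infinite-t sentinel with p = 0.

No multiple-testing correction is applied by default — the per-cell α = 0.05
flag mirrors the reference presentation — but a Holm step-down option
exists. Report cells round t and p to 2 decimals; raw values are always
retained in the machine-readable output.

The omnibus MANOVA (Wilks' Λ with F approximation, via statsmodels) treats
the eight joints' r values at one lag as the multivariate response. It
requires more subjects than response columns; at the study size (10
subjects, 8 joints) the error df is marginal, which is reported rather than
hidden. Identical group means short-circuit to p = 1 (Λ = 1 exactly).

## OKS scoring

`OKS = exp(−d²/(s²k²))` with d the Euclidean pixel distance between
predicted and ground-truth keypoint. The default constants are s = 1,
k = 0.001, matching the reference evaluation; note that with d in raw
pixels these constants drive the score to 0 for errors above ~0.01 px, so
the units of d behind the published 0.83–0.91 values are effectively
unrecoverable. The module therefore (a) keeps s and k fully configurable,
(b) offers normalization of d by the image diagonal, and (c) implements the
conventional COCO variant `exp(−d²/(2s²k²))` behind a `variant` flag
(default is the plain form above). Keypoints never visible in the ground
truth are excluded from their per-keypoint mean and flagged, not scored 0,
so annotation gaps are not conflated with model error.

Model-vs-model significance is a paired t-test across the 17 per-keypoint
means (df = 16): when only per-keypoint summaries are available, pairing on
keypoints is the reproducible choice. Both population and sample standard
deviations are reported for the 17-value aggregation because published
summaries mix the two conventions (0.031 vs 0.032 for the generic model's
column). Relative improvement is (mean_A − mean_B)/mean_B, which gives
10.2% for the published columns (the reported "9%" is consistent with
normalizing by the larger mean instead).

## Synthetic cohort generator

The generator produces the *statistical* structure the analysis assumes —
periodicity, inter-limb synchrony, extension bias, contrasting
autocorrelation decay — on a planar skeleton with a fixed torso. It makes
no claim of biomechanical fidelity.

**Normal class.** Each joint's angle series is a stationary
Ornstein–Uhlenbeck process (exact AR(1) discretization), stationary SD
`amplitude` = 0.45 cosine units, corner frequency `smoothness_bandwidth` =
0.25 Hz (timescale ≈ 0.64 s), mixed with a cohort-shared OU path with weight
`inter_limb_phase_coupling` = 0.15 (weak coupling), plus white measurement
noise (SD 0.03). Upper limbs get 1.5× the bandwidth, reflecting their
greater freedom of movement. The resulting r(k) decays to ≈ 0 within ~2 s.

**CS class.** Angle series are
`bias + tonic + oscillation + irregular + noise`:

* `extension_bias` = −0.35 shifts the baseline toward extension (cosine −1);
* the tonic term is a slow sinusoid (`tonic_amplitude` = 0.45,
  `tonic_period_s` = 60, random phase, shared across joints) modeling the
  waxing and waning of cramped episodes. Its ACF over the 1–13 s lag window
  is high, positive and nearly deterministic given the phase, which is what
  makes the CS autocorrelation profile high at every lag, gradually
  tapering, and consistent across subjects;
* the oscillation is a shared sinusoid (`amplitude` = 0.30,
  `oscillation_period_s` = 3 s — a free choice, no published movement
  frequency exists for CS GMs) whose per-joint phase offsets shrink by the
  coupling factor (0.9: near-synchronous limbs). Its phase diffuses as a
  Brownian walk (`phase_diffusion` = 0.5 rad²/s, coherence a few seconds):
  real flexion–extension cycles are not phase-locked over tens of seconds,
  so this term dominates r(k) near the 3 s period and vanishes from it at
  long lags. A phase-coherent fixed-period sinusoid would instead force
  r ≈ −0.5·(its variance share) at lags 5–13 s and make the long-lag ACF
  swing wildly between subjects under period jitter — the opposite of the
  observed CS pattern;
* `upper_limb_coupling` (default 0.15, the normal-class coupling level)
  sets how much of the stereotyped pattern reaches the upper limbs; the
  remainder is made up by normal-style irregular OU motion with matched
  variance. At the default, CS upper limbs are statistically
  indistinguishable from normal ones, reproducing the reported null result
  in the upper extremities;
* everything is clamped to [−1, 1]; with tonic amplitude, phase diffusion
  and noise all zero, the series is an exact sinusoid.

The variance budget (tonic 0.101, oscillation 0.045, noise 0.0009) puts the
population CS autocorrelation at ≈ 0.8/0.5/0.4/0.2/0.1 for lags
3/5/7/11/13 s versus ≈ 0 for the normal class, so the default 5-vs-5 cohort
has high power in the lower limbs at df = 8.

**Cohorts and determinism.** `generate_cohort` derives per-subject seeds
from a master seed via `numpy` seed sequences and jitters each subject's
period and amplitude by ±10%. Every generator output is a pure function of
its parameters and seed; regeneration is bit-identical. Default cohort
size is 5 + 5 subjects of 180 s at 30 fps, the reference study's
movement-analysis conditions.

**Forward kinematics.** Shoulders, hips and head keypoints are static at
layout positions (640×480 px frame); elbows are placed by rotating the
shoulder→hip direction by arccos of the shoulder series, wrists from the
elbow series, knees from the hip series (rotating hip→shoulder), ankles
from the knee series. Left and right limbs rotate with opposite signs, and
mirroring the layout flips them, so reflection symmetry is exact. Because
arccos inverts the cosine exactly, angles → keypoints → angles is the
identity to ~1e−7 (tested at 1e−6), and the layout validator guarantees
all keypoints stay inside the image for any cosine value.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: perspective and lens distortion, torso and head
motion, occlusion and detection dropout (available only via explicit
confidence manipulation or `perturb_keypoints`), poor-repertoire GMs,
correlations between left and right beyond the shared process, and any
physiological time structure beyond second-order statistics. Conclusions
about real NICU videos require real videos.

## Problem sizes and numerical choices

The simulation-based checks use the study-scale defaults: 50 master seeds ×
(5+5 subjects × 180 s × 30 fps) for the cohort significance rates, 2000
cells for type-I calibration, ~100k samples for Monte-Carlo OKS checks.
These sizes keep the full test suite and the acceptance script at a couple
of minutes on one CPU while leaving Monte-Carlo error well below the margins
tested. Ties in lag rounding go away from zero; cosine and r values are
clamped/bounded as described; degenerate inputs (constant series, zero-length
vectors, empty groups, singular covariances) raise typed errors rather than
propagating NaN.

## Known limitations

* The OKS constants' pixel-unit ambiguity (above) means published absolute
  OKS levels cannot be re-derived from first principles, only re-aggregated.
* The MANOVA at study size (10 subjects, 8 responses) has 1 error df after
  the F transform; its p values are reported but fragile.
* The per-cell t-tests are uncorrected for multiplicity by default (by
  design, to mirror the reference grid); use the Holm flag for inference.
* Angle extraction assumes a single infant, supine, filmed from above;
  multi-person scenes and viewpoint changes are out of scope.
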