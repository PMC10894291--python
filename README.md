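# gmamove

Movement-feature analysis of infant **general movements (GMs)** from 2D pose
keypoint time series.

Infants' spontaneous general movements in the writhing stage (from ~9 weeks
gestation to ~8 weeks post-term) carry strong prognostic signal for cerebral
palsy: **cramped-synchronized (CS)** GMs — rigid movements in which limbs and
trunk contract and relax almost simultaneously, biased toward extension — are
a high-risk pattern, while normal writhing GMs are variable and irregular.
Scoring GMs normally requires certified observers. `gmamove` implements the
quantitative end of an automated alternative: given per-frame 17-keypoint
(COCO-convention) pose estimates of a supine infant, it computes joint-angle
signals, summarizes their repetitiveness, and tests whether labeled cohorts
(normal vs CS) separate. It is aimed at researchers prototyping movement
models on NICU pose data — and, because clinical videos are private, it ships
a synthetic cohort generator so every pipeline stage runs and is testable
without patient data.

## What it computes

**Joint angles as cosine similarity.** Each of eight joints (left/right
elbow, shoulder, hip, knee) is an *anchor* keypoint with two limb-segment
vectors A, B rooted at it (e.g. left elbow → left shoulder and left elbow →
left wrist):

    d_cos(A, B) = (A · B) / (‖A‖ ‖B‖)

so +1 = fully flexed, 0 = right angle, −1 = fully extended. Tracked per frame
this gives one dimensionless angle series per joint.

**Normalized autocorrelation.** Repetitiveness of movement is measured by the
sample autocorrelation of each angle series at lag k frames,

    r(k) = Σ_{t=1..T−k} (y_t − ȳ)(y_{t+k} − ȳ) / Σ_{t=1..T} (y_t − ȳ)²

evaluated on a lag grid in seconds (default 1, 2, 3, 5, 7, 11, 13 s at the
video frame rate). r(0) = 1 exactly and |r(k)| ≤ 1. High r at long lags means
stereotyped, predictable movement — the CS signature.

**Group statistics.** Per (joint, lag) cell, an independent two-sample
pooled-variance Student t-test (df = n₁+n₂−2; Welch by flag) between cohorts,
reported as a lags × joints grid of `t (p)` cells, plus an optional omnibus
one-way MANOVA (Wilks' Λ) across the eight joints at a fixed lag.

**Keypoint accuracy (OKS).** Pose-model predictions are scored against
ground-truth annotations with object keypoint similarity,
`OKS = exp(−d²/(s²k²))` with scale `s` and per-keypoint fall-off `k`
(the conventional COCO form with the extra factor 2 is available behind a
flag), aggregated to per-keypoint means and model-vs-model paired
comparisons.

**Synthetic cohorts.** Normal GMs are simulated as weakly coupled
mean-reverting colored noise; CS GMs as an extension-biased, inter-limb
synchronized flexion–extension oscillation with a slow tonic cycle and
phase diffusion. A planar forward-kinematics skeleton converts angle series
to keypoint coordinates such that re-extracting angles is the identity to
float precision.

## Worked example

```python
from gmamove import (cohort_features, generate_cohort,
                     summarize_comparison, ttest_by_joint_lag)

cohort = generate_cohort(master_seed=1)          # 5 normal vs 5 CS, 180 s @ 30 fps
features = cohort_features(cohort.sequences)     # r per subject, joint, lag
grid, summary = summarize_comparison(ttest_by_joint_lag(features))
print(grid[["left_hip", "left_knee", "left_elbow"]].to_string())
```

prints (negative t = CS has the higher autocorrelation):

```
            left_hip      left_knee    left_elbow
lag_s
1.0    -15.19 (0.00)  -17.28 (0.00)  -0.61 (0.56)
2.0    -14.49 (0.00)  -11.44 (0.00)  -0.79 (0.45)
3.0    -36.03 (0.00)  -26.25 (0.00)   1.24 (0.25)
5.0    -11.32 (0.00)  -14.04 (0.00)  -0.87 (0.41)
7.0    -14.44 (0.00)  -15.65 (0.00)  -0.29 (0.78)
11.0    -6.02 (0.00)   -6.39 (0.00)  -0.27 (0.79)
13.0    -6.30 (0.00)   -5.19 (0.00)   0.65 (0.53)
```

The lower-limb cells are overwhelmingly significant while the elbow column
is null — the qualitative pattern reported for real normal-vs-CS cohorts,
where lower-extremity autocorrelation separates the groups at lags of a few
seconds and upper limbs do not. The `examples/` directory holds one short
narrative script per capability (`simulate_cohort.py`, `extract_features.py`,
`compare_groups.py`, `score_keypoints.py`); each prints what it computes and
what the numbers mean.

A thin CLI wraps the same API for shell use:

```
gmamove simulate --seed 1 --out cohort/
gmamove features cohort/*.csv --manifest cohort/manifest.yaml --out feats/
gmamove compare --features feats/acf.csv --out report/
gmamove evaluate-oks --truth gt.json --pred model=preds.json --out oks/
```

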