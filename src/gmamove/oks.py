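"""Object keypoint similarity (OKS) scoring of predicted poses.

OKS maps the Euclidean pixel error d of one predicted keypoint onto
(0, 1] via a Gaussian fall-off::

    OKS = exp(-d^2 / (s^2 * k^2))          ("paper" variant)
    OKS = exp(-d^2 / (2 * s^2 * k^2))      ("coco_standard" variant)

where ``s`` is an object scale and ``k`` a per-keypoint fall-off
constant.  The first form is the one used for the reported NICU model
accuracies (with s=1, k=0.001); the second carries the conventional
factor 2 of the COCO ecosystem.  Note that with s=1, k=0.001 and d in
raw pixels the score underflows for any error above ~0.01 px, so the
units of d in the reported accuracies are effectively a free parameter;
``OKSConfig.normalize_by_diagonal`` optionally divides d by the image
diagonal to make the constants usable on pixel data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .keypoints import KEYPOINT_NAMES, N_KEYPOINTS, AnnotationSet

__all__ = [
    "OKSConfig",
    "KeypointAccuracyReport",
    "ModelComparison",
    "EvaluationError",
    "oks_single",
    "evaluate_model",
    "aggregate_report",
    "compare_models",
]

Variant = Literal["paper", "coco_standard"]


class EvaluationError(ValueError):
    """The annotation set cannot support an OKS evaluation."""


@dataclass
class OKSConfig:
    """Constants of the OKS formula.

    ``k`` may be a scalar (applied to all 17 keypoints) or a length-17
    array of per-keypoint fall-off constants.
    """

    s: float = 1.0
    k: float | np.ndarray = 0.001
    variant: Variant = "paper"
    normalize_by_diagonal: bool = False

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError(f"s must be positive, got {self.s}")
        k = np.broadcast_to(np.asarray(self.k, dtype=float), (N_KEYPOINTS,)).copy()
        if np.any(k <= 0):
            raise ValueError("all fall-off constants k must be positive")
        self.k = k
        if self.variant not in ("paper", "coco_standard"):
            raise ValueError(f"unknown variant {self.variant!r}")


def oks_single(
    d: float, s: float = 1.0, k: float = 0.001, variant: Variant = "paper"
) -> float:
    """OKS of a single keypoint at pixel distance ``d`` from ground truth.

    Equals 1 iff d == 0 and decreases strictly (and continuously) in d.
    Scaling d and s by the same factor leaves the value unchanged.
    """
    if d < 0:
        raise ValueError(f"distance must be non-negative, got {d}")
    if s <= 0 or k <= 0:
        raise ValueError(f"s and k must be positive, got s={s}, k={k}")
    denom = s * s * k * k
    if variant == "coco_standard":
        denom *= 2.0
    elif variant != "paper":
        raise ValueError(f"unknown variant {variant!r}")
    return math.exp(-(d * d) / denom)


@dataclass
class KeypointAccuracyReport:
    """Per-keypoint mean OKS for one model against ground truth.

    ``per_keypoint`` holds 17 means in canonical keypoint order; entries
    for keypoints that were never visible in the ground truth are NaN and
    listed in ``excluded``.  ``mean`` is the arithmetic mean of the
    non-excluded per-keypoint values; both population and sample standard
    deviation conventions are reported.
    """

    model_name: str
    per_keypoint: np.ndarray
    n_frames: np.ndarray
    excluded: tuple[str, ...] = ()
    mean: float = field(init=False)
    std_population: float = field(init=False)
    std_sample: float = field(init=False)

    def __post_init__(self) -> None:
        self.per_keypoint = np.asarray(self.per_keypoint, dtype=float)
        self.n_frames = np.asarray(self.n_frames, dtype=int)
        if self.per_keypoint.shape != (N_KEYPOINTS,):
            raise ValueError("per_keypoint must hold 17 values")
        valid = self.per_keypoint[~np.isnan(self.per_keypoint)]
        if np.any((valid < 0) | (valid > 1)):
            raise ValueError("OKS values must lie in [0, 1]")
        self.mean = float(np.mean(valid))
        self.std_population = float(np.std(valid))
        self.std_sample = float(np.std(valid, ddof=1)) if valid.size > 1 else 0.0

    def as_dict(self) -> dict[str, float]:
        return dict(zip(KEYPOINT_NAMES, self.per_keypoint.tolist()))


def evaluate_model(
    ann: AnnotationSet, config: OKSConfig | None = None, model_name: str = "model"
) -> KeypointAccuracyReport:
    """Score an annotation set's predictions against its ground truth.

    For each keypoint the mean OKS is taken over the frames where the
    ground-truth confidence is positive; keypoints never visible in the
    ground truth are excluded (NaN) rather than scored zero, so
    annotation gaps are not conflated with model error.
    """
    config = config or OKSConfig()
    if not ann.predictions:
        raise EvaluationError("annotation set carries no predictions")

    sums = np.zeros(N_KEYPOINTS)
    counts = np.zeros(N_KEYPOINTS, dtype=int)
    for image_id, pred in ann.predictions.items():
        truth = ann.ground_truth[image_id]
        visible = truth.confidence > 0
        if not np.any(visible):
            continue
        d = np.linalg.norm(pred.xy - truth.xy, axis=1)
        if config.normalize_by_diagonal:
            w, h = ann.images[image_id]
            diag = math.hypot(w, h)
            if diag <= 0:
                raise EvaluationError(
                    f"image {image_id} has no usable width/height for "
                    "diagonal normalization"
                )
            d = d / diag
        denom = config.s**2 * config.k**2
        if config.variant == "coco_standard":
            denom = 2.0 * denom
        oks = np.exp(-(d**2) / denom)
        sums[visible] += oks[visible]
        counts[visible] += 1

    if counts.sum() == 0:
        raise EvaluationError("no visible ground-truth keypoints to evaluate")
    per_keypoint = np.full(N_KEYPOINTS, np.nan)
    per_keypoint[counts > 0] = sums[counts > 0] / counts[counts > 0]
    excluded = tuple(
        name for name, c in zip(KEYPOINT_NAMES, counts) if c == 0
    )
    return KeypointAccuracyReport(
        model_name=model_name,
        per_keypoint=per_keypoint,
        n_frames=counts,
        excluded=excluded,
    )


def aggregate_report(per_keypoint_values) -> tuple[float, float, float]:
    """Aggregate 17 per-keypoint means into (mean, population SD, sample SD).

    Both standard-deviation conventions are returned because published
    per-model summaries mix the two.
    """
    values = np.asarray(per_keypoint_values, dtype=float)
    if values.shape != (N_KEYPOINTS,):
        raise ValueError(f"expected exactly 17 values, got shape {values.shape}")
    if not np.all(np.isfinite(values)):
        raise ValueError("all 17 values must be finite")
    return float(np.mean(values)), float(np.std(values)), float(np.std(values, ddof=1))


@dataclass
class ModelComparison:
    """Paired comparison of two per-keypoint accuracy reports."""

    model_a: str
    model_b: str
    deltas: np.ndarray  # per keypoint, a minus b
    t_statistic: float
    p_value: float
    df: int
    relative_improvement: float  # (mean_a - mean_b) / mean_b


def compare_models(report_a: KeypointAccuracyReport, report_b: KeypointAccuracyReport) -> ModelComparison:
    """Paired t-test of two models across the 17 per-keypoint means.

    Pairing on keypoints is the reproducible choice when only the
    per-keypoint summary of each model is available.  Identical reports
    give t=0, p=1 by convention.
    """
    a, b = report_a.per_keypoint, report_b.per_keypoint
    paired = ~(np.isnan(a) | np.isnan(b))
    if np.isnan(a).any() != np.isnan(b).any() or not np.array_equal(
        np.isnan(a), np.isnan(b)
    ):
        raise ValueError("reports cover different keypoint subsets")
    if paired.sum() < 2:
        raise ValueError("need at least two paired keypoints")
    deltas = a[paired] - b[paired]
    if np.allclose(deltas, 0):
        t_stat, p = 0.0, 1.0
    else:
        res = stats.ttest_rel(a[paired], b[paired])
        t_stat, p = float(res.statistic), float(res.pvalue)
    mean_a, mean_b = float(np.mean(a[paired])), float(np.mean(b[paired]))
    return ModelComparison(
        model_a=report_a.model_name,
        model_b=report_b.model_name,
        deltas=a - b,
        t_statistic=t_stat,
        p_value=p,
        df=int(paired.sum() - 1),
        relative_improvement=(mean_a - mean_b) / mean_b,
    )
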