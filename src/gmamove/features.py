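"""Joint-angle cosine-similarity signals and their autocorrelation.

Each of eight joints (elbows, shoulders, hips, knees, both sides) is an
*anchor* keypoint with two limb-segment vectors rooted at it; the joint
angle is represented by the cosine similarity

    d_cos(A, B) = (A . B) / (||A|| ||B||)

of those vectors, so +1 means a fully flexed joint, 0 a right angle and
-1 full extension.  Tracking d_cos per frame yields one angle time
series per joint; repetitiveness of movement is then summarized by the
normalized sample autocorrelation

    r(k) = sum_{t=1}^{T-k} (y_t - ybar)(y_{t+k} - ybar)
           / sum_{t=1}^{T} (y_t - ybar)^2

evaluated on a lag grid expressed in seconds (default 1, 2, 3, 5, 7,
11, 13 s).  r(0) = 1 exactly and |r(k)| <= 1 by Cauchy-Schwarz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .keypoints import KEYPOINT_INDEX, PoseSequence

__all__ = [
    "JointAnchor",
    "AngleSeries",
    "AutocorrelationProfile",
    "JOINT_ORDER",
    "DEFAULT_LAGS_S",
    "DegenerateGeometryError",
    "DegenerateSeriesError",
    "EmptySeriesError",
    "canonical_anchors",
    "cosine_similarity",
    "angle_timeseries",
    "normalized_autocorrelation",
    "acf_profile",
    "lag_to_frames",
    "sequence_angle_series",
    "sequence_acf_profiles",
    "angles_to_tidy",
    "profiles_to_tidy",
]

#: Canonical joint order used in tabular reports (right/left pairs,
#: proximal-to-distal: elbows, shoulders, hips, knees).
JOINT_ORDER = (
    "right_elbow", "left_elbow", "right_shoulder", "left_shoulder",
    "right_hip", "left_hip", "right_knee", "left_knee",
)

#: Default lag grid, seconds.
DEFAULT_LAGS_S = (1.0, 2.0, 3.0, 5.0, 7.0, 11.0, 13.0)


class DegenerateGeometryError(ValueError):
    """Coincident keypoints produced a zero-length limb vector."""


class DegenerateSeriesError(ValueError):
    """A constant (zero-variance) series has no defined autocorrelation."""


class EmptySeriesError(ValueError):
    """No usable observations remain in an angle series."""


@dataclass(frozen=True)
class JointAnchor:
    """A joint keypoint plus the two endpoint keypoints of its vectors."""

    name: str
    anchor: str
    endpoint_a: str
    endpoint_b: str

    def __post_init__(self) -> None:
        names = (self.anchor, self.endpoint_a, self.endpoint_b)
        if len(set(names)) != 3:
            raise ValueError(f"{self.name}: anchor and endpoints must be distinct")
        for n in names:
            if n not in KEYPOINT_INDEX:
                raise ValueError(f"{self.name}: unknown keypoint {n!r}")


def canonical_anchors() -> list[JointAnchor]:
    """The eight canonical joint anchors, in :data:`JOINT_ORDER`.

    Elbow vectors point to the shoulder and wrist, knee vectors to the
    hip and ankle; shoulder and hip anchors use their anatomically
    adjacent joints (shoulder: elbow + hip, hip: knee + shoulder).
    """
    def make(side: str, joint: str, a: str, b: str) -> JointAnchor:
        return JointAnchor(
            name=f"{side}_{joint}",
            anchor=f"{side}_{joint}",
            endpoint_a=f"{side}_{a}",
            endpoint_b=f"{side}_{b}",
        )

    anchors = {
        f"{side}_{joint}": make(side, joint, a, b)
        for side in ("right", "left")
        for joint, a, b in (
            ("elbow", "shoulder", "wrist"),
            ("shoulder", "elbow", "hip"),
            ("hip", "knee", "shoulder"),
            ("knee", "hip", "ankle"),
        )
    }
    return [anchors[name] for name in JOINT_ORDER]


def cosine_similarity(a, b) -> float:
    """Cosine of the angle between two 2D vectors, clamped to [-1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise DegenerateGeometryError("zero-length vector (coincident keypoints)")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


@dataclass
class AngleSeries:
    """Per-frame cosine-similarity values for one joint (NaN = missing)."""

    joint: str
    values: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 - 1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError(f"{self.joint}: cosine values outside [-1, 1]")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_missing(self) -> int:
        return int(np.sum(~np.isfinite(self.values)))


def _interpolate_short_gaps(values: np.ndarray, max_gap: int) -> np.ndarray:
    """Linearly fill interior NaN runs of length <= max_gap."""
    out = values.copy()
    if max_gap < 1:
        return out
    isnan = ~np.isfinite(out)
    if not isnan.any() or isnan.all():
        return out
    # locate NaN runs
    idx = np.flatnonzero(isnan)
    run_starts = idx[np.r_[True, np.diff(idx) > 1]]
    run_ends = idx[np.r_[np.diff(idx) > 1, True]]
    for s, e in zip(run_starts, run_ends):
        length = e - s + 1
        if s == 0 or e == len(out) - 1 or length > max_gap:
            continue  # edge runs and long runs stay missing
        left, right = out[s - 1], out[e + 1]
        out[s : e + 1] = left + (right - left) * np.arange(1, length + 1) / (length + 1)
    return out


def angle_timeseries(
    seq: PoseSequence,
    anchor: JointAnchor,
    min_confidence: float = 0.0,
    max_gap_frames: int = 5,
) -> AngleSeries:
    """Extract one joint's cosine-similarity series from a pose sequence.

    Per frame, A = endpoint_a - anchor and B = endpoint_b - anchor.
    Frames where any of the three keypoints falls below
    ``min_confidence`` (or a vector degenerates to zero length) are
    missing; interior missing runs of at most ``max_gap_frames`` frames
    are linearly interpolated, longer runs stay missing.
    """
    if len(seq) == 0:
        raise EmptySeriesError(f"{seq.subject_id}: empty sequence")
    xy = seq.coords()
    conf = seq.confidences()
    ia = KEYPOINT_INDEX[anchor.anchor]
    ja = KEYPOINT_INDEX[anchor.endpoint_a]
    jb = KEYPOINT_INDEX[anchor.endpoint_b]

    A = xy[:, ja] - xy[:, ia]
    B = xy[:, jb] - xy[:, ia]
    na = np.linalg.norm(A, axis=1)
    nb = np.linalg.norm(B, axis=1)
    # min_confidence == 0 still masks conf == 0 (never-detected points)
    conf_ok = np.minimum(np.minimum(conf[:, ia], conf[:, ja]), conf[:, jb])
    bad = (conf_ok < min_confidence) | (conf_ok <= 0) | (na == 0) | (nb == 0)

    with np.errstate(invalid="ignore", divide="ignore"):
        cosv = np.einsum("ij,ij->i", A, B) / (na * nb)
    cosv = np.clip(cosv, -1.0, 1.0)
    cosv[bad] = np.nan
    cosv = _interpolate_short_gaps(cosv, max_gap_frames)
    if not np.isfinite(cosv).any():
        raise EmptySeriesError(
            f"{seq.subject_id}/{anchor.name}: all frames missing"
        )
    return AngleSeries(joint=anchor.name, values=cosv, fps=seq.fps)


def normalized_autocorrelation(values, lag_frames: int) -> float:
    """Normalized sample autocorrelation at an integer frame lag.

    Uses the standard estimator with the full-series mean and variance in
    the denominator, so r(0) = 1 exactly and |r(k)| <= 1 for every lag.
    Missing values (NaN) are ignored: the denominator sums over all
    non-missing deviations and the numerator over lag-k pairs with both
    members present (which preserves the |r| <= 1 bound).
    """
    y = np.asarray(values, dtype=float)
    T = len(y)
    if lag_frames < 0:
        raise ValueError(f"lag must be non-negative, got {lag_frames}")
    if lag_frames >= T:
        raise ValueError(f"lag {lag_frames} >= series length {T}")
    ok = np.isfinite(y)
    n_obs = int(ok.sum())
    if n_obs < lag_frames + 2:
        raise ValueError(
            f"need at least lag+2 = {lag_frames + 2} observations, have {n_obs}"
        )
    ybar = y[ok].mean()
    dev = y - ybar
    denom = float(np.sum(dev[ok] ** 2))
    if denom == 0.0:
        raise DegenerateSeriesError("constant series: autocorrelation undefined")
    if lag_frames == 0:
        return 1.0
    d0 = dev[: T - lag_frames]
    dk = dev[lag_frames:]
    both = np.isfinite(d0) & np.isfinite(dk)
    num = float(np.sum(d0[both] * dk[both]))
    return num / denom


def lag_to_frames(lag_s: float, fps: float) -> int:
    """Convert a lag in seconds to frames, rounding half away from zero."""
    if fps <= 0:
        raise ValueError(f"fps must be positive, got {fps}")
    x = lag_s * fps
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass
class AutocorrelationProfile:
    """r(k) for one joint over a lag grid in seconds."""

    joint: str
    lags_s: tuple[float, ...]
    r: np.ndarray
    n_obs: int
    series_mean: float

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        if np.any(np.abs(self.r) > 1 + 1e-12):
            raise ValueError(f"{self.joint}: |r| must not exceed 1")


def acf_profile(
    series: AngleSeries,
    lags_s=DEFAULT_LAGS_S,
    fps: float | None = None,
) -> AutocorrelationProfile:
    """Autocorrelation of an angle series at each lag of a grid in seconds.

    ``fps`` defaults to the frame rate carried on the series.
    """
    fps = series.fps if fps is None else fps
    lags_s = tuple(float(l) for l in lags_s)
    r = np.array(
        [normalized_autocorrelation(series.values, lag_to_frames(l, fps)) for l in lags_s]
    )
    ok = np.isfinite(series.values)
    return AutocorrelationProfile(
        joint=series.joint,
        lags_s=lags_s,
        r=r,
        n_obs=int(ok.sum()),
        series_mean=float(series.values[ok].mean()),
    )


# ---------------------------------------------------------------------------
# Whole-sequence helpers and tidy exports
# ---------------------------------------------------------------------------

def sequence_angle_series(
    seq: PoseSequence,
    anchors: list[JointAnchor] | None = None,
    min_confidence: float = 0.0,
    max_gap_frames: int = 5,
) -> dict[str, AngleSeries]:
    """All eight joints' angle series for one sequence, keyed by joint."""
    anchors = anchors or canonical_anchors()
    return {
        a.name: angle_timeseries(seq, a, min_confidence, max_gap_frames)
        for a in anchors
    }


def sequence_acf_profiles(
    seq: PoseSequence,
    lags_s=DEFAULT_LAGS_S,
    min_confidence: float = 0.0,
    max_gap_frames: int = 5,
) -> dict[str, AutocorrelationProfile]:
    """ACF profiles of all eight joints for one sequence."""
    series = sequence_angle_series(seq, None, min_confidence, max_gap_frames)
    return {name: acf_profile(s, lags_s) for name, s in series.items()}


def angles_to_tidy(subject_id: str, series: dict[str, AngleSeries]) -> pd.DataFrame:
    """Tidy frame-level table: subject, joint, frame, value."""
    parts = [
        pd.DataFrame(
            {
                "subject": subject_id,
                "joint": name,
                "frame": np.arange(len(s)),
                "value": s.values,
            }
        )
        for name, s in series.items()
    ]
    return pd.concat(parts, ignore_index=True)


def profiles_to_tidy(
    subject_id: str,
    profiles: dict[str, AutocorrelationProfile],
    label: str | None = None,
) -> pd.DataFrame:
    """Tidy lag-level table: subject [, label], joint, lag_s, r."""
    parts = []
    for name, p in profiles.items():
        d = {
            "subject": subject_id,
            "joint": name,
            "lag_s": list(p.lags_s),
            "r": p.r,
        }
        if label is not None:
            d["label"] = label
        parts.append(pd.DataFrame(d))
    return pd.concat(parts, ignore_index=True)
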