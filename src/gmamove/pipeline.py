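"""Glue between pose sequences and the cohort-level statistics."""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .features import DEFAULT_LAGS_S, profiles_to_tidy, sequence_acf_profiles
from .keypoints import PoseSequence
from .stats import CohortFeatures

__all__ = ["cohort_feature_table", "cohort_features"]


def cohort_feature_table(
    sequences: Iterable[PoseSequence],
    lags_s: Sequence[float] = DEFAULT_LAGS_S,
    min_confidence: float = 0.0,
    max_gap_frames: int = 5,
) -> pd.DataFrame:
    """Tidy table of per-subject, per-joint autocorrelation features.

    Columns: subject, label, joint, lag_s, r.
    """
    parts = []
    for seq in sequences:
        profiles = sequence_acf_profiles(
            seq, lags_s, min_confidence=min_confidence, max_gap_frames=max_gap_frames
        )
        parts.append(
            profiles_to_tidy(seq.subject_id, profiles, label=seq.gma_label.value)
        )
    if not parts:
        raise ValueError("no sequences given")
    return pd.concat(parts, ignore_index=True)


def cohort_features(
    sequences: Iterable[PoseSequence],
    lags_s: Sequence[float] = DEFAULT_LAGS_S,
    min_confidence: float = 0.0,
    max_gap_frames: int = 5,
) -> CohortFeatures:
    """Subjects-by-(joint, lag) feature matrix ready for group tests."""
    return CohortFeatures.from_tidy(
        cohort_feature_table(sequences, lags_s, min_confidence, max_gap_frames)
    )
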