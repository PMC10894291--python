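"""Reported summary statistics from a NICU writhing-stage GM study.

These are the printed per-keypoint OKS accuracies of a generic
COCO-pretrained pose model versus a NICU-fine-tuned model, the reported
group-comparison t statistics (normal vs cramped-synchronized cohorts,
5 videos each, pooled two-sample t with 8 degrees of freedom), and the
reported video-length statistics.  They serve as fixed numeric inputs
for re-aggregation checks: the underlying clinical videos are private,
so only this printed summary level is reproducible.
"""

from __future__ import annotations

import numpy as np

from .keypoints import KEYPOINT_NAMES

__all__ = [
    "REPORTED_OKS_GENERIC",
    "REPORTED_OKS_NICU",
    "REPORTED_GROUP_T",
    "REPORTED_GROUP_P",
    "REPORTED_LAGS_S",
    "JOINT_COLUMNS",
    "VIDEO_FRAME_COUNT_MEAN",
    "VIDEO_FRAME_COUNT_SD",
    "VIDEO_FPS",
    "OKS_SCALE",
    "OKS_FALLOFF",
]

#: Reported per-keypoint mean OKS of the generic (COCO-pretrained) model,
#: in canonical keypoint order.
REPORTED_OKS_GENERIC = dict(
    zip(
        KEYPOINT_NAMES,
        [0.83, 0.85, 0.87, 0.80, 0.80, 0.86, 0.87, 0.87, 0.86, 0.83, 0.85,
         0.81, 0.80, 0.80, 0.78, 0.80, 0.79],
    )
)

#: Reported per-keypoint mean OKS of the NICU-fine-tuned model.
REPORTED_OKS_NICU = dict(
    zip(
        KEYPOINT_NAMES,
        [0.91, 0.92, 0.92, 0.89, 0.91, 0.92, 0.92, 0.91, 0.92, 0.91, 0.92,
         0.91, 0.90, 0.91, 0.92, 0.91, 0.91],
    )
)

#: Joint-column order of the reported group-comparison grid.
JOINT_COLUMNS = (
    "right_elbow", "left_elbow", "right_shoulder", "left_shoulder",
    "right_hip", "left_hip", "right_knee", "left_knee",
)

#: Lag grid (seconds) of the reported group comparison.
REPORTED_LAGS_S = (1, 2, 3, 5, 7, 11, 13)

#: Reported t statistics (normal minus cramped-synchronized), rows = lags
#: in REPORTED_LAGS_S order, columns = JOINT_COLUMNS order.
REPORTED_GROUP_T = np.array([
    [0.82, -0.98, -1.36, -0.62, -2.04, -1.89, -1.91, -0.93],
    [0.42, -1.65, -1.26, -0.38, -2.36, -1.89, -2.39, -1.23],
    [0.50, -1.83, -1.16, -0.29, -2.59, -2.04, -2.83, -1.61],
    [0.43, -1.51, -0.91, -0.40, -3.16, -2.49, -3.46, -2.32],
    [0.75, -1.30, -0.98, -0.16, -3.61, -2.72, -3.65, -2.34],
    [0.49, -0.86, -1.10, -0.00, -3.56, -2.60, -4.20, -2.46],
    [0.72, -0.56, -1.02, 0.04, -3.60, -2.45, -4.27, -2.21],
])

#: Reported two-sided p values paired with REPORTED_GROUP_T (printed at
#: 1-2 decimals).
REPORTED_GROUP_P = np.array([
    [0.44, 0.35, 0.21, 0.55, 0.08, 0.10, 0.09, 0.38],
    [0.68, 0.14, 0.24, 0.71, 0.05, 0.10, 0.04, 0.25],
    [0.63, 0.11, 0.28, 0.78, 0.03, 0.08, 0.02, 0.15],
    [0.68, 0.17, 0.39, 0.70, 0.01, 0.04, 0.01, 0.05],
    [0.47, 0.23, 0.35, 0.88, 0.01, 0.03, 0.01, 0.05],
    [0.64, 0.41, 0.30, 1.00, 0.01, 0.03, 0.00, 0.04],
    [0.49, 0.59, 0.34, 0.97, 0.01, 0.04, 0.00, 0.06],
])

#: Reported video length, frames (mean +/- SD) at the stated frame rate.
VIDEO_FRAME_COUNT_MEAN = 5370.93
VIDEO_FRAME_COUNT_SD = 1353.28
VIDEO_FPS = 30.0

#: OKS constants used for the reported keypoint accuracies.
OKS_SCALE = 1.0
OKS_FALLOFF = 0.001
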