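"""Data model and I/O for 17-keypoint infant pose time series.

The keypoint vocabulary and ordering follow the COCO person-keypoint
convention (nose, eyes, ears, shoulders, elbows, wrists, hips, knees,
ankles), which is also the vocabulary used for annotating supine infants
in the NICU.  Two serialized forms are supported:

* COCO keypoint JSON (``images`` / ``annotations`` / ``categories``
  arrays with 51-value ``keypoints`` vectors) for annotation sets used
  in pose-model evaluation;
* a flat CSV dialect (``frame``, then ``<name>_x``, ``<name>_y``,
  ``<name>_conf`` per keypoint) for per-video time series.

Coordinates are 0-based pixels, x rightward, y downward.  Ground-truth
confidence is fixed at 1.0; COCO visibility flags 0/1/2 map to
confidence 0 / 0.5 / 1.0 so downstream masking only ever deals with a
single scalar channel.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KEYPOINT_NAMES",
    "N_KEYPOINTS",
    "GmaLabel",
    "KeypointFrame",
    "PoseSequence",
    "AnnotationSet",
    "KeypointFormatError",
    "SequenceValidationError",
    "read_coco_keypoints",
    "write_coco_keypoints",
    "read_timeseries_csv",
    "write_timeseries_csv",
    "sample_annotation_frames",
]

#: The 17 anatomical keypoints in canonical COCO order.  This ordering is
#: load-bearing: every serialized array indexes into it.
KEYPOINT_NAMES: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)

N_KEYPOINTS = len(KEYPOINT_NAMES)

KEYPOINT_INDEX: dict[str, int] = {name: i for i, name in enumerate(KEYPOINT_NAMES)}

#: COCO visibility flag -> scalar confidence.
_VISIBILITY_TO_CONFIDENCE = {0: 0.0, 1: 0.5, 2: 1.0}


class GmaLabel(str, Enum):
    """General Movement Assessment class of a video."""

    NORMAL = "normal"
    POOR_REPERTOIRE = "poor_repertoire"
    CRAMPED_SYNCHRONIZED = "cramped_synchronized"
    UNKNOWN = "unknown"


class KeypointFormatError(ValueError):
    """A serialized keypoint file violates the expected format."""


class SequenceValidationError(ValueError):
    """A pose sequence violates a structural invariant."""


@dataclass
class KeypointFrame:
    """One frame's 17 keypoint locations with per-keypoint confidence.

    ``xy`` is a float array of shape (17, 2) in pixels; ``confidence`` is
    a float array of shape (17,) in [0, 1].  Coordinates must be finite
    wherever confidence is positive.
    """

    frame_index: int
    xy: np.ndarray
    confidence: np.ndarray

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.frame_index < 0:
            raise SequenceValidationError(
                f"frame_index must be non-negative, got {self.frame_index}"
            )
        if self.xy.shape != (N_KEYPOINTS, 2):
            raise SequenceValidationError(
                f"xy must have shape (17, 2), got {self.xy.shape}"
            )
        if self.confidence.shape != (N_KEYPOINTS,):
            raise SequenceValidationError(
                f"confidence must have shape (17,), got {self.confidence.shape}"
            )
        if np.any((self.confidence < 0) | (self.confidence > 1)):
            raise SequenceValidationError("confidence values must lie in [0, 1]")
        visible = self.confidence > 0
        if not np.all(np.isfinite(self.xy[visible])):
            raise SequenceValidationError(
                f"frame {self.frame_index}: non-finite coordinates at visible keypoints"
            )

    def allclose(self, other: "KeypointFrame", atol: float = 1e-6) -> bool:
        return (
            self.frame_index == other.frame_index
            and np.allclose(self.xy, other.xy, atol=atol, equal_nan=True)
            and np.allclose(self.confidence, other.confidence, atol=atol)
        )


@dataclass
class PoseSequence:
    """An ordered per-frame keypoint time series for one video."""

    subject_id: str
    frames: list[KeypointFrame]
    fps: float = 30.0
    gma_label: GmaLabel = GmaLabel.UNKNOWN

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise SequenceValidationError(f"fps must be positive, got {self.fps}")
        self.gma_label = GmaLabel(self.gma_label)
        indices = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise SequenceValidationError(
                f"frame indices must be strictly increasing for {self.subject_id!r}"
            )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def duration_s(self) -> float:
        """Sequence duration in seconds (frame count over frame rate)."""
        return len(self.frames) / self.fps

    def coords(self) -> np.ndarray:
        """Stacked coordinates, shape (T, 17, 2)."""
        if not self.frames:
            return np.empty((0, N_KEYPOINTS, 2))
        return np.stack([f.xy for f in self.frames])

    def confidences(self) -> np.ndarray:
        """Stacked confidences, shape (T, 17)."""
        if not self.frames:
            return np.empty((0, N_KEYPOINTS))
        return np.stack([f.confidence for f in self.frames])

    @classmethod
    def from_arrays(
        cls,
        subject_id: str,
        xy: np.ndarray,
        confidence: np.ndarray | None = None,
        fps: float = 30.0,
        gma_label: GmaLabel | str = GmaLabel.UNKNOWN,
    ) -> "PoseSequence":
        """Build a sequence from a (T, 17, 2) coordinate array."""
        xy = np.asarray(xy, dtype=float)
        if confidence is None:
            confidence = np.ones(xy.shape[:2])
        frames = [
            KeypointFrame(t, xy[t], confidence[t]) for t in range(xy.shape[0])
        ]
        return cls(subject_id, frames, fps=fps, gma_label=GmaLabel(gma_label))

    def allclose(self, other: "PoseSequence", atol: float = 1e-6) -> bool:
        return (
            self.subject_id == other.subject_id
            and math.isclose(self.fps, other.fps)
            and self.gma_label == other.gma_label
            and len(self) == len(other)
            and all(a.allclose(b, atol=atol) for a, b in zip(self.frames, other.frames))
        )


@dataclass
class AnnotationSet:
    """Ground-truth (and optionally predicted) keypoints per image.

    ``images`` maps image id -> (width, height) in pixels.  Predictions,
    when present, must refer to images present in the ground truth.
    """

    images: dict[int, tuple[int, int]]
    ground_truth: dict[int, KeypointFrame]
    predictions: dict[int, KeypointFrame] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing_img = set(self.ground_truth) - set(self.images)
        if missing_img:
            raise SequenceValidationError(
                f"ground-truth annotations refer to unknown images: {sorted(missing_img)}"
            )
        orphans = set(self.predictions) - set(self.ground_truth)
        if orphans:
            raise SequenceValidationError(
                f"predictions refer to images absent from ground truth: {sorted(orphans)}"
            )

    def allclose(self, other: "AnnotationSet", atol: float = 1e-6) -> bool:
        if self.images != other.images:
            return False
        if set(self.ground_truth) != set(other.ground_truth):
            return False
        if set(self.predictions) != set(other.predictions):
            return False
        return all(
            self.ground_truth[i].allclose(other.ground_truth[i], atol=atol)
            for i in self.ground_truth
        ) and all(
            self.predictions[i].allclose(other.predictions[i], atol=atol)
            for i in self.predictions
        )


# ---------------------------------------------------------------------------
# COCO keypoint JSON
# ---------------------------------------------------------------------------

def _frame_from_coco_triplets(image_id: int, values: Sequence[float], record: str) -> KeypointFrame:
    if len(values) != 3 * N_KEYPOINTS:
        raise KeypointFormatError(
            f"{record}: expected {3 * N_KEYPOINTS} keypoint values "
            f"(17 x,y,v triplets), got {len(values)}"
        )
    arr = np.asarray(values, dtype=float).reshape(N_KEYPOINTS, 3)
    conf = np.empty(N_KEYPOINTS)
    for i, v in enumerate(arr[:, 2]):
        if v in _VISIBILITY_TO_CONFIDENCE:
            conf[i] = _VISIBILITY_TO_CONFIDENCE[v]
        elif 0.0 <= v <= 1.0:  # prediction scores are already confidences
            conf[i] = v
        else:
            raise KeypointFormatError(
                f"{record}: keypoint visibility/score {v} is neither a COCO "
                "flag (0/1/2) nor a confidence in [0,1]"
            )
    xy = arr[:, :2].copy()
    xy[conf == 0] = np.nan
    return KeypointFrame(frame_index=int(image_id), xy=xy, confidence=conf)


def read_coco_keypoints(path: str | Path, predictions_path: str | Path | None = None) -> AnnotationSet:
    """Read a COCO-style keypoint JSON file into an :class:`AnnotationSet`.

    ``predictions_path`` may point at either a second COCO file or a bare
    COCO "results" list of ``{image_id, keypoints, ...}`` records; its
    keypoint triplet third elements are interpreted as confidences when
    they are not 0/1/2 visibility flags.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise KeypointFormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(payload, dict) or "annotations" not in payload:
        raise KeypointFormatError(f"{path}: missing 'annotations' array")

    images: dict[int, tuple[int, int]] = {}
    for img in payload.get("images", []):
        images[int(img["id"])] = (int(img["width"]), int(img["height"]))

    ground_truth: dict[int, KeypointFrame] = {}
    for ann in payload["annotations"]:
        if "keypoints" not in ann:
            raise KeypointFormatError(
                f"{path}: annotation id={ann.get('id', '?')} has no 'keypoints'"
            )
        image_id = int(ann["image_id"])
        record = f"{path.name}: annotation id={ann.get('id', '?')}"
        ground_truth[image_id] = _frame_from_coco_triplets(
            image_id, ann["keypoints"], record
        )
        if image_id not in images:
            images[image_id] = (0, 0)

    predictions: dict[int, KeypointFrame] = {}
    if predictions_path is not None:
        predictions_path = Path(predictions_path)
        try:
            pred_payload = json.loads(predictions_path.read_text())
        except json.JSONDecodeError as exc:
            raise KeypointFormatError(
                f"{predictions_path}: not valid JSON ({exc})"
            ) from exc
        records = (
            pred_payload["annotations"]
            if isinstance(pred_payload, dict)
            else pred_payload
        )
        for ann in records:
            image_id = int(ann["image_id"])
            record = f"{predictions_path.name}: prediction image_id={image_id}"
            predictions[image_id] = _frame_from_coco_triplets(
                image_id, ann["keypoints"], record
            )

    return AnnotationSet(images=images, ground_truth=ground_truth, predictions=predictions)


def _coco_triplets(frame: KeypointFrame) -> list[float]:
    values: list[float] = []
    for (x, y), c in zip(frame.xy, frame.confidence):
        if c <= 0:
            values.extend([0.0, 0.0, 0])
        else:
            v = 2 if c > 0.75 else 1
            values.extend([float(x), float(y), v])
    return values


def write_coco_keypoints(ann: AnnotationSet, path: str | Path) -> None:
    """Write the ground truth of an :class:`AnnotationSet` as COCO JSON."""
    payload = {
        "images": [
            {"id": i, "width": w, "height": h, "file_name": f"frame_{i:06d}.png"}
            for i, (w, h) in sorted(ann.images.items())
        ],
        "annotations": [
            {
                "id": n + 1,
                "image_id": image_id,
                "category_id": 1,
                "keypoints": _coco_triplets(frame),
                "num_keypoints": int(np.sum(frame.confidence > 0)),
            }
            for n, (image_id, frame) in enumerate(sorted(ann.ground_truth.items()))
        ],
        "categories": [
            {"id": 1, "name": "infant", "keypoints": list(KEYPOINT_NAMES), "skeleton": []}
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# CSV time-series dialect
# ---------------------------------------------------------------------------

def _csv_columns() -> list[str]:
    cols = ["frame"]
    for name in KEYPOINT_NAMES:
        cols.extend([f"{name}_x", f"{name}_y", f"{name}_conf"])
    return cols


def read_timeseries_csv(
    path: str | Path,
    fps: float = 30.0,
    subject_id: str | None = None,
    gma_label: GmaLabel | str = GmaLabel.UNKNOWN,
) -> PoseSequence:
    """Read a pose time series from the flat CSV dialect.

    The file must carry a ``frame`` column plus ``<name>_x``, ``<name>_y``
    and ``<name>_conf`` for each of the 17 keypoint names, in any column
    order.  Frame indices must be strictly increasing.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _csv_columns() if c not in df.columns]
    if missing:
        raise KeypointFormatError(f"{path}: missing columns {missing}")
    frames: list[KeypointFrame] = []
    for _, row in df.iterrows():
        xy = np.array(
            [[row[f"{n}_x"], row[f"{n}_y"]] for n in KEYPOINT_NAMES], dtype=float
        )
        conf = np.array([row[f"{n}_conf"] for n in KEYPOINT_NAMES], dtype=float)
        frames.append(KeypointFrame(int(row["frame"]), xy, conf))
    return PoseSequence(
        subject_id=subject_id if subject_id is not None else path.stem,
        frames=frames,
        fps=fps,
        gma_label=GmaLabel(gma_label),
    )


def write_timeseries_csv(seq: PoseSequence, path: str | Path) -> None:
    """Write a :class:`PoseSequence` in the flat CSV dialect.

    Coordinates and confidences are serialized with 6 decimals, enough
    for a bit-stable round trip at that precision.
    """
    rows = []
    for f in seq.frames:
        row: dict[str, float | int] = {"frame": f.frame_index}
        for i, name in enumerate(KEYPOINT_NAMES):
            x, y = f.xy[i]
            row[f"{name}_x"] = 0.0 if not np.isfinite(x) else x
            row[f"{name}_y"] = 0.0 if not np.isfinite(y) else y
            row[f"{name}_conf"] = f.confidence[i]
        rows.append(row)
    df = pd.DataFrame(rows, columns=_csv_columns())
    df.to_csv(path, index=False, float_format="%.6f")


def sample_annotation_frames(
    seq: PoseSequence, step: int, max_frames: int | None = None
) -> list[KeypointFrame]:
    """Subsample frames for annotation: positions 0, step, 2*step, ...

    This mirrors the study practice of annotating every ``step``-th frame
    of a video (e.g. 10 frames from a 100-frame video at step 10), with
    an optional cap on the number of frames returned.
    """
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    if max_frames is not None and max_frames < 1:
        raise ValueError(f"max_frames must be >= 1, got {max_frames}")
    picked = seq.frames[::step]
    if max_frames is not None:
        picked = picked[:max_frames]
    return list(picked)
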