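"""Object keypoint similarity: score a noisy pose model vs ground truth.

Treats a synthetic sequence as ground truth and a Gaussian-jittered
copy (sigma = 2 px) as a pose model's predictions, scores it with
OKS = exp(-d^2/(s^2 k^2)), and re-aggregates the published per-keypoint
accuracy columns of the NICU-trained vs generic pose models.
"""

import numpy as np

from gmamove import (
    AnnotationSet,
    MovementParams,
    OKSConfig,
    aggregate_report,
    angles_to_keypoints,
    evaluate_model,
    perturb_keypoints,
    simulate_subject_angles,
)
from gmamove.reference import REPORTED_OKS_GENERIC, REPORTED_OKS_NICU

truth = angles_to_keypoints(
    simulate_subject_angles(MovementParams.normal_defaults(duration_s=20.0, seed=11))
)
pred = perturb_keypoints(truth, jitter_sd=2.0, seed=12)
ann = AnnotationSet(
    images={f.frame_index: (640, 480) for f in truth.frames},
    ground_truth={f.frame_index: f for f in truth.frames},
    predictions={f.frame_index: f for f in pred.frames},
)
report = evaluate_model(ann, OKSConfig(s=1.0, k=20.0), model_name="jittered")
print(f"jittered model: mean OKS = {report.mean:.4f} "
      f"(closed form for sigma=2, sk=20 is {1 / (1 + 2 * 4 / 400):.4f})")

mean_n, sd_n, _ = aggregate_report(list(REPORTED_OKS_NICU.values()))
mean_g, sd_g, _ = aggregate_report(list(REPORTED_OKS_GENERIC.values()))
print(f"published per-keypoint columns re-aggregate to "
      f"{mean_n:.2f} +/- {sd_n:.3f} (NICU-trained) vs "
      f"{mean_g:.2f} +/- {sd_g:.3f} (generic)")
print()
print("The jittered model's mean OKS matches the Gaussian closed form;")
print("the published columns reproduce the reported 0.91 vs 0.83 contrast.")
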