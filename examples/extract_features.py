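"""Joint-angle cosine signals and their autocorrelation for one subject.

Simulates one cramped-synchronized subject, extracts the eight
joint-angle cosine-similarity series from its keypoints, and prints the
normalized autocorrelation r(k) on the standard lag grid (seconds).
High r at long lags means repetitive, predictable movement.
"""

import numpy as np

from gmamove import (
    MovementParams,
    angles_to_keypoints,
    sequence_acf_profiles,
    simulate_subject_angles,
)

params = MovementParams.cs_defaults(duration_s=120.0, seed=3)
seq = angles_to_keypoints(simulate_subject_angles(params))

lags = (1.0, 2.0, 3.0, 5.0, 7.0, 11.0, 13.0)
profiles = sequence_acf_profiles(seq, lags_s=lags)

print(f"subject: cramped-synchronized, {len(seq)} frames at {seq.fps:g} fps")
print("lag (s):   " + "  ".join(f"{l:5g}" for l in lags))
for joint, profile in profiles.items():
    cells = "  ".join(f"{r:5.2f}" for r in profile.r)
    print(f"{joint:15s} {cells}")
print()
print("Lower-limb rows (hips, knees) keep r well above 0 out to 13 s --")
print("the repetitive movement signature; the bump at 3 s is the")
print("oscillation period of the stereotyped flexion-extension cycle.")
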