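"""Generate a small labeled synthetic cohort and inspect its structure.

Builds 2 normal + 2 cramped-synchronized (CS) 30-second pose sequences
at 30 fps and prints per-subject metadata.  Each sequence is a full
17-keypoint planar skeleton whose joint angles follow the class model:
irregular colored noise for normal general movements, a synchronized
extension-biased oscillation with a slow tonic cycle for CS.
"""

from gmamove import MovementParams, generate_cohort

cohort = generate_cohort(
    n_per_group=2,
    params_normal=MovementParams.normal_defaults(duration_s=30.0),
    params_cs=MovementParams.cs_defaults(duration_s=30.0),
    master_seed=7,
)

print(f"cohort of {len(cohort.sequences)} sequences (master seed {cohort.master_seed})")
for seq in cohort.sequences:
    xy = seq.coords()
    print(
        f"  {seq.subject_id:10s} label={seq.gma_label.value:22s} "
        f"frames={len(seq)} fps={seq.fps:g} "
        f"x-span=[{xy[..., 0].min():.0f}, {xy[..., 0].max():.0f}] px"
    )
print("per-subject seeds:", cohort.seed_registry)
print()
print("The x-span shows limb excursions across the image; regenerating with")
print("the same master seed reproduces these sequences bit-for-bit.")
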