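"""Synthetic labeled cohorts of infant pose sequences.

The study's clinical videos are private, so this module generates
cohorts with the *statistical* structure the analysis assumes, not
biomechanical fidelity: a planar 17-keypoint skeleton with a fixed
torso, driven by per-joint cosine-similarity angle processes.

Normal general movements are modeled as irregular, weakly coupled
mean-reverting colored noise (exact-discretized Ornstein-Uhlenbeck),
so their angle autocorrelation decays within a couple of seconds.
Cramped-synchronized (CS) movements combine

* an extension bias (baseline shifted toward cosine -1),
* a slow tonic posture cycle shared by all participating joints
  (sinusoid with a ~60 s period and random phase, modeling the waxing
  and waning of cramped episodes) -- this is what makes the CS
  autocorrelation high at every lag and gradually tapering, and keeps
  it stable between subjects,
* a shared flexion-extension oscillation whose per-joint phase offsets
  shrink as inter-limb coupling rises; its phase diffuses as a random
  walk (movement oscillations are only coherent over a few seconds),
  so this component dominates the autocorrelation near the oscillation
  period and vanishes from it at long lags, and
* additive noise.

Upper limbs participate in the stereotyped CS pattern only to the
degree set by ``upper_limb_coupling``; at its default (the normal-class
coupling level) CS upper limbs move essentially like normal ones,
mirroring the reported absence of group differences in the upper
extremities.  With ``tonic_amplitude``, ``phase_diffusion`` and
``noise_sd`` all zero, a CS series reduces to an exact sinusoid.

Angle series are converted to keypoint coordinates by forward
kinematics constructed so that re-extracting angles from the generated
keypoints reproduces the input series to floating-point precision.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.signal import lfilter

from .features import JOINT_ORDER, AngleSeries
from .keypoints import (
    KEYPOINT_INDEX,
    KEYPOINT_NAMES,
    N_KEYPOINTS,
    GmaLabel,
    PoseSequence,
)

__all__ = [
    "MovementParams",
    "InfantLayout",
    "SyntheticCohort",
    "LOWER_LIMB_JOINTS",
    "simulate_angle_series",
    "simulate_subject_angles",
    "angles_to_keypoints",
    "generate_cohort",
    "perturb_keypoints",
]

#: Joints carrying the full CS stereotypy.
LOWER_LIMB_JOINTS = frozenset(
    {"right_hip", "left_hip", "right_knee", "left_knee"}
)

#: Fixed per-joint phase offsets (radians) for the CS sinusoid, spread
#: over the cycle so that zero coupling means fully desynchronized limbs.
_JOINT_PHASE = {name: 2.0 * np.pi * i / 8.0 for i, name in enumerate(JOINT_ORDER)}


@dataclass
class MovementParams:
    """Parameters of one subject's angle dynamics.

    ``amplitude`` is the stationary standard deviation of the normal-class
    OU process, or the CS sinusoid amplitude, in cosine units.
    ``smoothness_bandwidth`` is the corner frequency (Hz) of the colored
    noise; the OU timescale is 1 / (2 pi bandwidth).
    """

    gma_class: str = "normal"
    duration_s: float = 180.0
    fps: float = 30.0
    oscillation_period_s: float = 3.0
    amplitude: float = 0.45
    inter_limb_phase_coupling: float = 0.15
    upper_limb_coupling: float = 0.15
    extension_bias: float = 0.0
    noise_sd: float = 0.03
    smoothness_bandwidth: float = 0.25
    upper_limb_bandwidth_factor: float = 1.5
    tonic_amplitude: float = 0.0
    tonic_period_s: float = 60.0
    phase_diffusion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gma_class not in ("normal", "cramped_synchronized"):
            raise ValueError(f"unknown gma_class {self.gma_class!r}")
        if min(self.duration_s, self.fps, self.oscillation_period_s) <= 0:
            raise ValueError("duration_s, fps and oscillation_period_s must be positive")
        for name in ("inter_limb_phase_coupling", "upper_limb_coupling"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not -1.0 <= self.extension_bias <= 0.0:
            raise ValueError(f"extension_bias must lie in [-1, 0], got {self.extension_bias}")
        if min(self.noise_sd, self.tonic_amplitude, self.amplitude, self.phase_diffusion) < 0:
            raise ValueError(
                "amplitude, noise_sd, tonic_amplitude and phase_diffusion must be non-negative"
            )
        if self.smoothness_bandwidth <= 0 or self.tonic_period_s <= 0:
            raise ValueError("smoothness_bandwidth and tonic_period_s must be positive")

    @classmethod
    def normal_defaults(cls, **overrides) -> "MovementParams":
        """Irregular, weakly coupled movement typical of normal GMs."""
        return cls(gma_class="normal", **overrides)

    @classmethod
    def cs_defaults(cls, **overrides) -> "MovementParams":
        """Stereotyped, synchronized, extension-biased CS movement."""
        base = dict(
            gma_class="cramped_synchronized",
            amplitude=0.30,
            inter_limb_phase_coupling=0.9,
            extension_bias=-0.35,
            tonic_amplitude=0.45,
            phase_diffusion=0.5,
        )
        base.update(overrides)
        return cls(**base)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


def _stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent deterministic stream per (seed, stream-name)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=[int(seed), zlib.crc32(stream.encode())])
    )


def _ou_series(rng: np.random.Generator, T: int, dt: float, tau: float, sd: float) -> np.ndarray:
    """Stationary OU sample path via its exact AR(1) discretization."""
    if sd == 0.0:
        return np.zeros(T)
    a = np.exp(-dt / tau)
    eps = rng.standard_normal(T)
    u = sd * np.sqrt(1.0 - a * a) * eps
    u[0] = sd * eps[0]  # draw x_0 from the stationary law
    return lfilter([1.0], [1.0, -a], u)


def simulate_angle_series(params: MovementParams, joint: str) -> AngleSeries:
    """One joint's cosine-similarity series under the class model.

    A pure function of (params, joint): shared components (tonic drift,
    global sinusoid phase, shared normal-class OU) are drawn from a
    stream keyed by ``params.seed`` alone, so the eight joints of one
    subject are mutually consistent however they are generated.
    """
    if joint not in JOINT_ORDER:
        raise ValueError(f"unknown joint {joint!r}")
    T = params.n_frames
    dt = 1.0 / params.fps
    upper = joint not in LOWER_LIMB_JOINTS
    shared = _stream_rng(params.seed, "shared")
    own = _stream_rng(params.seed, f"joint:{joint}")

    bw = params.smoothness_bandwidth * (
        params.upper_limb_bandwidth_factor if upper else 1.0
    )
    tau = 1.0 / (2.0 * np.pi * bw)

    if params.gma_class == "normal":
        # shared stream order: one shared OU path
        shared_ou = _ou_series(
            shared, T, dt, 1.0 / (2.0 * np.pi * params.smoothness_bandwidth), params.amplitude
        )
        own_ou = _ou_series(own, T, dt, tau, params.amplitude)
        c = params.inter_limb_phase_coupling
        x = params.extension_bias + c * shared_ou + np.sqrt(1.0 - c * c) * own_ou
    else:
        # shared stream order: tonic phase, oscillation phase, phase walk
        psi_tonic = shared.uniform(0.0, 2.0 * np.pi)
        psi = shared.uniform(0.0, 2.0 * np.pi)
        t = np.arange(T) * dt
        if params.phase_diffusion > 0:
            walk = np.cumsum(
                np.sqrt(params.phase_diffusion * dt) * shared.standard_normal(T)
            )
        else:
            walk = np.zeros(T)
        tonic = params.tonic_amplitude * np.sin(
            2.0 * np.pi * t / params.tonic_period_s + psi_tonic
        )
        phase_offset = (1.0 - params.inter_limb_phase_coupling) * _JOINT_PHASE[joint]
        sinus = params.amplitude * np.sin(
            2.0 * np.pi * t / params.oscillation_period_s + psi + walk + phase_offset
        )
        stereotyped = tonic + sinus
        w = 1.0 if not upper else params.upper_limb_coupling
        sd_irregular = np.sqrt((params.tonic_amplitude**2 + params.amplitude**2) / 2.0)
        irregular = _ou_series(own, T, dt, tau, sd_irregular)
        x = params.extension_bias * w + w * stereotyped + np.sqrt(1.0 - w * w) * irregular

    if params.noise_sd > 0:
        x = x + params.noise_sd * own.standard_normal(T)
    return AngleSeries(joint=joint, values=np.clip(x, -1.0, 1.0), fps=params.fps)


def simulate_subject_angles(params: MovementParams) -> dict[str, AngleSeries]:
    """All eight joints' angle series for one subject."""
    return {joint: simulate_angle_series(params, joint) for joint in JOINT_ORDER}


# ---------------------------------------------------------------------------
# Forward kinematics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InfantLayout:
    """Planar skeleton geometry (pixels) of a supine infant.

    The torso (shoulders, hips) and head keypoints are static; limb
    keypoints are placed by forward kinematics from the angle series.
    ``handedness`` (+1/-1) mirrors the skeleton about the vertical
    midline, flipping limb rotation directions accordingly.
    """

    image_width: int = 640
    image_height: int = 480
    center_x: float = 320.0
    shoulder_y: float = 160.0
    hip_y: float = 300.0
    shoulder_width: float = 90.0
    hip_width: float = 60.0
    upper_arm: float = 70.0
    lower_arm: float = 65.0
    thigh: float = 75.0
    shank: float = 70.0
    head_y: float = 110.0
    eye_dx: float = 18.0
    eye_dy: float = -10.0
    ear_dx: float = 33.0
    handedness: int = 1

    def __post_init__(self) -> None:
        lengths = (
            self.shoulder_width, self.hip_width, self.upper_arm,
            self.lower_arm, self.thigh, self.shank,
        )
        if any(v <= 0 for v in lengths):
            raise ValueError("all segment lengths must be positive")
        if self.handedness not in (1, -1):
            raise ValueError("handedness must be +1 or -1")
        # limb reach must stay inside the frame for any angle
        arm_reach = self.upper_arm + self.lower_arm
        leg_reach = self.thigh + self.shank
        sx = self.shoulder_width / 2.0
        hx = self.hip_width / 2.0
        if (
            self.center_x - sx - arm_reach < 0
            or self.center_x + sx + arm_reach > self.image_width
            or self.shoulder_y - arm_reach < 0
            or self.shoulder_y + arm_reach > self.image_height
            or self.center_x - hx - leg_reach < 0
            or self.center_x + hx + leg_reach > self.image_width
            or self.hip_y - leg_reach < 0
            or self.hip_y + leg_reach > self.image_height
        ):
            raise ValueError("limb reach exceeds image bounds for this layout")

    def mirrored(self) -> "InfantLayout":
        """The left-right mirror image of this layout."""
        return replace(self, handedness=-self.handedness)

    def static_positions(self) -> dict[str, np.ndarray]:
        """Pixel positions of torso and head keypoints."""
        h = self.handedness
        cx = self.center_x
        return {
            "nose": np.array([cx, self.head_y]),
            "left_eye": np.array([cx + h * self.eye_dx, self.head_y + self.eye_dy]),
            "right_eye": np.array([cx - h * self.eye_dx, self.head_y + self.eye_dy]),
            "left_ear": np.array([cx + h * self.ear_dx, self.head_y]),
            "right_ear": np.array([cx - h * self.ear_dx, self.head_y]),
            "left_shoulder": np.array([cx + h * self.shoulder_width / 2, self.shoulder_y]),
            "right_shoulder": np.array([cx - h * self.shoulder_width / 2, self.shoulder_y]),
            "left_hip": np.array([cx + h * self.hip_width / 2, self.hip_y]),
            "right_hip": np.array([cx - h * self.hip_width / 2, self.hip_y]),
        }


def _rotate(vec: np.ndarray, theta: np.ndarray, sign: float) -> np.ndarray:
    """Rotate 2D vector(s) by sign*theta. vec (2,) or (T,2); theta (T,)."""
    c, s = np.cos(theta), np.sin(sign * theta)
    x, y = (vec[..., 0], vec[..., 1])
    return np.stack([x * c - y * s, x * s + y * c], axis=-1)


def _unit(vec: np.ndarray) -> np.ndarray:
    norm = np.linalg.norm(vec, axis=-1, keepdims=True)
    return vec / norm


def angles_to_keypoints(
    angles: Mapping[str, AngleSeries], layout: InfantLayout | None = None
) -> PoseSequence:
    """Place keypoints so each joint's cosine angle matches its series.

    The torso and head are static at the layout positions.  Elbows hang
    off the shoulder-angle series (rotation of the shoulder->hip
    direction), wrists off the elbow series, knees off the hip series
    (rotation of hip->shoulder) and ankles off the knee series.  Left
    and right limbs rotate in opposite directions so the rest posture is
    symmetric.  Re-extracting angles from the output recovers every
    input series to ~1e-7.
    """
    layout = layout or InfantLayout()
    missing = [j for j in JOINT_ORDER if j not in angles]
    if missing:
        raise ValueError(f"missing angle series for joints: {missing}")
    lengths = {len(angles[j]) for j in JOINT_ORDER}
    fpss = {angles[j].fps for j in JOINT_ORDER}
    if len(lengths) != 1 or len(fpss) != 1:
        raise ValueError("all eight angle series must share length and fps")
    T = lengths.pop()
    fps = fpss.pop()
    for j in JOINT_ORDER:
        if not np.all(np.isfinite(angles[j].values)):
            raise ValueError(f"{j}: angle series has missing values")

    static = layout.static_positions()
    xy = np.empty((T, N_KEYPOINTS, 2))
    for name, pos in static.items():
        xy[:, KEYPOINT_INDEX[name]] = pos

    for side, sign in (("left", 1.0), ("right", -1.0)):
        sgn = sign * layout.handedness
        shoulder = static[f"{side}_shoulder"]
        hip = static[f"{side}_hip"]

        theta_sh = np.arccos(np.clip(angles[f"{side}_shoulder"].values, -1, 1))
        u = _unit(hip - shoulder)
        elbow = shoulder + layout.upper_arm * _rotate(u, theta_sh, sgn)

        theta_el = np.arccos(np.clip(angles[f"{side}_elbow"].values, -1, 1))
        v = _unit(shoulder - elbow)
        wrist = elbow + layout.lower_arm * _rotate(v, theta_el, sgn)

        theta_hip = np.arccos(np.clip(angles[f"{side}_hip"].values, -1, 1))
        w = _unit(shoulder - hip)
        knee = hip + layout.thigh * _rotate(w, theta_hip, sgn)

        theta_kn = np.arccos(np.clip(angles[f"{side}_knee"].values, -1, 1))
        z = _unit(hip - knee)
        ankle = knee + layout.shank * _rotate(z, theta_kn, sgn)

        xy[:, KEYPOINT_INDEX[f"{side}_elbow"]] = elbow
        xy[:, KEYPOINT_INDEX[f"{side}_wrist"]] = wrist
        xy[:, KEYPOINT_INDEX[f"{side}_knee"]] = knee
        xy[:, KEYPOINT_INDEX[f"{side}_ankle"]] = ankle

    return PoseSequence.from_arrays("synthetic", xy, fps=fps)


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """A labeled set of synthetic pose sequences with its seed registry.

    Regenerating with the same master seed and parameters is
    bit-identical.
    """

    sequences: list[PoseSequence]
    seed_registry: dict[str, int]
    params_normal: MovementParams
    params_cs: MovementParams
    layout: InfantLayout
    master_seed: int

    def by_label(self, label: GmaLabel | str) -> list[PoseSequence]:
        label = GmaLabel(label)
        return [s for s in self.sequences if s.gma_label == label]


def generate_cohort(
    n_per_group: int = 5,
    params_normal: MovementParams | None = None,
    params_cs: MovementParams | None = None,
    layout: InfantLayout | None = None,
    master_seed: int = 0,
) -> SyntheticCohort:
    """Generate n normal plus n cramped-synchronized pose sequences.

    Per-subject seeds are derived deterministically from ``master_seed``;
    each subject's oscillation period and amplitude are jittered by
    +/-10% for between-subject realism.
    """
    if n_per_group < 1:
        raise ValueError(f"n_per_group must be >= 1, got {n_per_group}")
    params_normal = params_normal or MovementParams.normal_defaults()
    params_cs = params_cs or MovementParams.cs_defaults()
    layout = layout or InfantLayout()

    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(2 * n_per_group + 1)
    jitter_rng = np.random.default_rng(children[-1])

    sequences: list[PoseSequence] = []
    registry: dict[str, int] = {}
    specs = [("normal", params_normal, GmaLabel.NORMAL)] * n_per_group + [
        ("cs", params_cs, GmaLabel.CRAMPED_SYNCHRONIZED)
    ] * n_per_group
    for i, (prefix, base, label) in enumerate(specs):
        subject_id = f"{prefix}_{i % n_per_group:02d}"
        seed = int(children[i].generate_state(1)[0] % 2**31)
        jit_period, jit_amp = 1.0 + jitter_rng.uniform(-0.1, 0.1, size=2)
        params = replace(
            base,
            seed=seed,
            oscillation_period_s=base.oscillation_period_s * jit_period,
            amplitude=base.amplitude * jit_amp,
        )
        seq = angles_to_keypoints(simulate_subject_angles(params), layout)
        seq.subject_id = subject_id
        seq.gma_label = label
        sequences.append(seq)
        registry[subject_id] = seed
    return SyntheticCohort(
        sequences=sequences,
        seed_registry=registry,
        params_normal=params_normal,
        params_cs=params_cs,
        layout=layout,
        master_seed=master_seed,
    )


def perturb_keypoints(seq: PoseSequence, jitter_sd: float, seed: int = 0) -> PoseSequence:
    """Add isotropic Gaussian pixel noise to every keypoint of every frame.

    Emulates pose-estimation error: per-keypoint displacement distances
    follow a Rayleigh law with scale ``jitter_sd``.
    """
    if jitter_sd < 0:
        raise ValueError(f"jitter_sd must be non-negative, got {jitter_sd}")
    if jitter_sd == 0:
        return PoseSequence(
            subject_id=seq.subject_id,
            frames=list(seq.frames),
            fps=seq.fps,
            gma_label=seq.gma_label,
        )
    rng = np.random.default_rng(seed)
    xy = seq.coords() + rng.normal(0.0, jitter_sd, size=(len(seq), N_KEYPOINTS, 2))
    conf = seq.confidences()
    out = PoseSequence.from_arrays(
        seq.subject_id, xy, confidence=conf, fps=seq.fps, gma_label=seq.gma_label
    )
    for f_out, f_in in zip(out.frames, seq.frames):
        f_out.frame_index = f_in.frame_index
    return out
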