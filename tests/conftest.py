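import numpy as np
import pytest

from gmamove import (
    InfantLayout,
    MovementParams,
    PoseSequence,
    angles_to_keypoints,
    simulate_subject_angles,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def layout():
    return InfantLayout()


@pytest.fixture
def short_cs_sequence(layout):
    """A 30 s cramped-synchronized pose sequence at 30 fps."""
    params = MovementParams.cs_defaults(duration_s=30.0, seed=7)
    return angles_to_keypoints(simulate_subject_angles(params), layout)


@pytest.fixture
def short_normal_sequence(layout):
    params = MovementParams.normal_defaults(duration_s=30.0, seed=8)
    return angles_to_keypoints(simulate_subject_angles(params), layout)


@pytest.fixture
def random_walk_sequence(rng):
    """A small sequence with smooth random keypoint motion, conf 1."""
    T = 40
    base = rng.uniform(100, 400, size=(17, 2))
    steps = rng.normal(0, 2.0, size=(T, 17, 2)).cumsum(axis=0)
    return PoseSequence.from_arrays("walk", base + steps, fps=30.0)
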