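import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gmamove import (
    JOINT_ORDER,
    AngleSeries,
    PoseSequence,
    acf_profile,
    angle_timeseries,
    canonical_anchors,
    cosine_similarity,
    normalized_autocorrelation,
)
from gmamove.features import (
    DegenerateGeometryError,
    DegenerateSeriesError,
    EmptySeriesError,
    lag_to_frames,
)
from gmamove.keypoints import KEYPOINT_INDEX


def acf_loop_oracle(y, k):
    """Independent double-loop estimator of the normalized autocorrelation.

    Ignores missing (NaN) observations: the denominator runs over all
    non-missing deviations, the numerator over pairs with both present.
    """
    y = np.asarray(y, dtype=float)
    obs = [v for v in y if math.isfinite(v)]
    ybar = sum(obs) / len(obs)
    denom = 0.0
    for v in obs:
        denom += (v - ybar) ** 2
    num = 0.0
    for t in range(len(y) - k):
        a, b = y[t], y[t + k]
        if math.isfinite(a) and math.isfinite(b):
            num += (a - ybar) * (b - ybar)
    return num / denom


class TestCanonicalAnchors:
    def test_eight_anchors_in_report_order(self):
        anchors = canonical_anchors()
        assert [a.name for a in anchors] == list(JOINT_ORDER)

    @pytest.mark.parametrize(
        "joint, endpoint_a, endpoint_b",
        [
            ("left_elbow", "left_shoulder", "left_wrist"),
            ("right_elbow", "right_shoulder", "right_wrist"),
            ("right_knee", "right_hip", "right_ankle"),
            ("left_shoulder", "left_elbow", "left_hip"),
            ("right_hip", "right_knee", "right_shoulder"),
        ],
    )
    def test_anchor_endpoints(self, joint, endpoint_a, endpoint_b):
        anchor = {a.name: a for a in canonical_anchors()}[joint]
        assert anchor.anchor == joint
        assert {anchor.endpoint_a, anchor.endpoint_b} == {endpoint_a, endpoint_b}


class TestCosineSimilarity:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1, 0), (0, 1), 0.0),  # perpendicular
            ((2, 3), (4, 6), 1.0),  # collinear, same direction
            ((1, 0), (-5, 0), -1.0),  # opposite
            ((1, 0), (1, 1), math.sqrt(2) / 2),  # 45 degrees
        ],
    )
    def test_reference_angles(self, a, b, expected):
        assert cosine_similarity(a, b) == pytest.approx(expected, abs=1e-12)

    def test_zero_vector_is_degenerate(self):
        with pytest.raises(DegenerateGeometryError):
            cosine_similarity((0, 0), (1, 1))


class TestAngleTimeseries:
    def _sequence_with_left_arm(self, shoulder, elbow, wrist):
        xy = np.tile(np.arange(17, dtype=float)[:, None] * 10 + 50, (1, 2))
        xy = np.stack([xy[:, 0], xy[:, 1]], axis=1)
        xy[KEYPOINT_INDEX["left_shoulder"]] = shoulder
        xy[KEYPOINT_INDEX["left_elbow"]] = elbow
        xy[KEYPOINT_INDEX["left_wrist"]] = wrist
        return PoseSequence.from_arrays("arm", xy[None, :, :], fps=30.0)

    def _left_elbow_anchor(self):
        return {a.name: a for a in canonical_anchors()}["left_elbow"]

    def test_right_angle_elbow_gives_zero(self):
        seq = self._sequence_with_left_arm((0, 0), (0, 10), (10, 10))
        series = angle_timeseries(seq, self._left_elbow_anchor())
        assert series.values[0] == pytest.approx(0.0, abs=1e-12)

    def test_fully_extended_arm_gives_minus_one(self):
        seq = self._sequence_with_left_arm((0, 0), (10, 10), (20, 20))
        series = angle_timeseries(seq, self._left_elbow_anchor())
        assert series.values[0] == pytest.approx(-1.0, abs=1e-12)

    @given(seed=st.integers(0, 10**6))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_similarity_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        xy = rng.uniform(50, 450, size=(6, 17, 2))
        seq = PoseSequence.from_arrays("orig", xy, fps=30.0)
        theta = rng.uniform(0, 2 * np.pi)
        scale = rng.uniform(0.2, 5.0)
        shift = rng.uniform(-100, 100, size=2)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        xy2 = scale * xy @ R.T + shift
        seq2 = PoseSequence.from_arrays("moved", xy2, fps=30.0)
        for anchor in canonical_anchors():
            s1 = angle_timeseries(seq, anchor).values
            s2 = angle_timeseries(seq2, anchor).values
            assert np.allclose(s1, s2, atol=1e-9)

    def test_mirror_maps_left_series_onto_right(self, rng):
        xy = rng.uniform(50, 450, size=(10, 17, 2))
        seq = PoseSequence.from_arrays("orig", xy, fps=30.0)
        # reflect x and swap left/right keypoints: the mirrored skeleton
        mirrored = xy.copy()
        mirrored[..., 0] = 500.0 - mirrored[..., 0]
        swap = np.arange(17)
        for i, name in enumerate(
            ["nose", "left_eye", "right_eye", "left_ear", "right_ear",
             "left_shoulder", "right_shoulder", "left_elbow", "right_elbow",
             "left_wrist", "right_wrist", "left_hip", "right_hip",
             "left_knee", "right_knee", "left_ankle", "right_ankle"]
        ):
            if name.startswith("left_"):
                swap[i] = KEYPOINT_INDEX["right_" + name[5:]]
            elif name.startswith("right_"):
                swap[i] = KEYPOINT_INDEX["left_" + name[6:]]
        seq_m = PoseSequence.from_arrays("mirror", mirrored[:, swap], fps=30.0)
        anchors = {a.name: a for a in canonical_anchors()}
        for joint in JOINT_ORDER:
            other = joint.replace("left", "R").replace("right", "left").replace("R", "right")
            s1 = angle_timeseries(seq, anchors[joint]).values
            s2 = angle_timeseries(seq_m, anchors[other]).values
            assert np.allclose(s1, s2, atol=0)

    def test_low_confidence_gap_interpolated_and_long_gap_kept_missing(self, rng):
        T = 30
        xy = rng.uniform(50, 450, size=(T, 17, 2))
        conf = np.ones((T, 17))
        ie = KEYPOINT_INDEX["left_elbow"]
        conf[5:8, ie] = 0.1  # 3-frame gap: interpolated at default max_gap=5
        conf[15:25, ie] = 0.1  # 10-frame gap: stays missing
        seq = PoseSequence.from_arrays("gaps", xy, confidence=conf, fps=30.0)
        anchor = {a.name: a for a in canonical_anchors()}["left_elbow"]
        series = angle_timeseries(seq, anchor, min_confidence=0.5)
        assert np.all(np.isfinite(series.values[5:8]))
        assert np.all(~np.isfinite(series.values[15:25]))
        # interpolation is linear between the bracketing frames
        left, right = series.values[4], series.values[8]
        assert series.values[6] == pytest.approx((left + right) / 2, abs=1e-12)

    def test_all_frames_missing_raises(self, rng):
        xy = rng.uniform(50, 450, size=(5, 17, 2))
        conf = np.zeros((5, 17))
        seq = PoseSequence.from_arrays("none", xy, confidence=conf, fps=30.0)
        anchor = canonical_anchors()[0]
        with pytest.raises(EmptySeriesError):
            angle_timeseries(seq, anchor)


class TestNormalizedAutocorrelation:
    def test_lag_zero_is_exactly_one(self, rng):
        y = rng.normal(size=500)
        assert normalized_autocorrelation(y, 0) == 1.0

    def test_alternating_series_lag_one(self):
        y = np.tile([1.0, -1.0], 50)  # length 100
        r = normalized_autocorrelation(y, 1)
        assert r == pytest.approx(-0.99, abs=1e-12)
        assert r == pytest.approx(-(len(y) - 1) / len(y), abs=1e-12)

    @pytest.mark.parametrize("T", [50, 313, 2000])
    @pytest.mark.parametrize("k", [1, 7, 48])
    def test_agrees_with_double_loop_oracle(self, rng, T, k):
        y = rng.normal(size=T)
        assert normalized_autocorrelation(y, k) == pytest.approx(
            acf_loop_oracle(y, k), abs=1e-12
        )

    def test_missing_data_agrees_with_oracle_and_stays_bounded(self, rng):
        y = rng.normal(size=400)
        y[rng.choice(400, size=60, replace=False)] = np.nan
        for k in (1, 5, 20):
            r = normalized_autocorrelation(y, k)
            assert abs(r) <= 1.0
            assert r == pytest.approx(acf_loop_oracle(y, k), abs=1e-12)

    def test_sinusoid_at_its_period(self, rng):
        P, T = 30, 9000
        y = np.sin(2 * np.pi * np.arange(T) / P)
        r = normalized_autocorrelation(y, P)
        assert r == pytest.approx(acf_loop_oracle(y, P), abs=1e-12)
        assert r == pytest.approx(1 - P / T, abs=1e-3)

    def test_bounded_for_random_series(self, rng):
        for _ in range(50):
            y = rng.standard_t(df=3, size=200)
            for k in (1, 3, 50, 198):
                assert abs(normalized_autocorrelation(y, k)) <= 1.0

    def test_ar1_autocorrelation_recovers_coefficient(self, rng):
        phi, T = 0.9, 9000
        eps = rng.normal(size=T)
        y = np.empty(T)
        y[0] = eps[0] / math.sqrt(1 - phi**2)
        for t in range(1, T):
            y[t] = phi * y[t - 1] + eps[t]
        for k in (1, 2, 3, 5):
            assert normalized_autocorrelation(y, k) == pytest.approx(
                phi**k, abs=0.05
            )

    def test_degenerate_inputs_raise(self):
        with pytest.raises(DegenerateSeriesError):
            normalized_autocorrelation(np.full(100, 3.0), 1)
        with pytest.raises(ValueError, match="lag"):
            normalized_autocorrelation(np.arange(10.0), 10)
        y = np.full(20, np.nan)
        y[:4] = [1.0, 2.0, 1.5, 2.5]
        with pytest.raises(ValueError, match="observations"):
            normalized_autocorrelation(y, 5)


class TestAcfProfile:
    @pytest.mark.parametrize(
        "lag_s, fps, expected",
        [(1, 30, 30), (2, 30, 60), (13, 30, 390), (0.05, 30, 2), (1, 29.97, 30)],
    )
    def test_lag_to_frames_rounds_half_away_from_zero(self, lag_s, fps, expected):
        assert lag_to_frames(lag_s, fps) == expected

    def test_default_grid_in_frames(self):
        assert [lag_to_frames(l, 30) for l in (1, 2, 3, 5, 7, 11, 13)] == [
            30, 60, 90, 150, 210, 330, 390,
        ]

    def test_lag_zero_profile(self, rng):
        series = AngleSeries("left_knee", rng.uniform(-1, 1, 200), fps=30.0)
        profile = acf_profile(series, lags_s=[0.0])
        assert profile.r[0] == 1.0

    def test_white_noise_profile_within_independence_band(self, rng):
        # +/- 2.58/sqrt(T) covers the sample ACF of white noise at 99%
        T = 5400
        series = AngleSeries("left_knee", np.clip(rng.normal(0, 0.3, T), -1, 1), 30.0)
        profile = acf_profile(series)
        assert np.all(np.abs(profile.r) < 0.05)

    def test_fps_carried_on_series(self, rng):
        series = AngleSeries("left_hip", rng.uniform(-1, 1, 1000), fps=10.0)
        profile = acf_profile(series, lags_s=[2.0])
        assert profile.r[0] == pytest.approx(
            normalized_autocorrelation(series.values, 20), abs=0
        )
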