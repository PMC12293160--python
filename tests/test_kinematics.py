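"""Kinematic measures: arithmetic, analytic oracles and similarity invariance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jawprobe import (
    KinematicsError,
    SubPeriodInterval,
    derivative_series,
    extract_subperiods,
    measurement_series,
    mouth_opening_series,
    pogonion_lateral_series,
    range_of_motion,
    time_normalize,
)
from jawprobe.kinematics import SUBPERIOD_INTERVALS, load_interval_table
from jawprobe.cohort import CANONICAL_WORDS, landmark_index
from tests.conftest import make_trajectory


def similarity(angle, scale, shift):
    c, s = np.cos(angle), np.sin(angle)
    return scale * np.array([[c, -s], [s, c]]), np.asarray(shift, float)


class TestMouthOpening:
    def test_ratio_arithmetic(self):
        traj = make_trajectory(mouth_width=40.0, heights=[20.0, 20.0])
        np.testing.assert_allclose(mouth_opening_series(traj), [2.0, 2.0])

    def test_unit_ratio_at_equal_width_and_height(self):
        traj = make_trajectory(mouth_width=30.0, heights=[30.0, 30.0])
        np.testing.assert_allclose(mouth_opening_series(traj), [1.0, 1.0])

    def test_height_over_width_convention(self):
        traj = make_trajectory(mouth_width=40.0, heights=[20.0, 10.0])
        np.testing.assert_allclose(
            mouth_opening_series(traj, convention="height_over_width"), [0.5, 0.25]
        )

    def test_closure_floored_at_epsilon(self):
        traj = make_trajectory(mouth_width=80.0, heights=[0.0, 20.0])
        series = mouth_opening_series(traj)
        assert np.isfinite(series).all()
        # floor = 1e-3 * face_width(200) = 0.2 px
        assert series[0] == pytest.approx(80.0 / 0.2)

    def test_coincident_cheilion_rejected(self):
        traj = make_trajectory(mouth_width=0.0, heights=[20.0, 20.0])
        with pytest.raises(KinematicsError, match="cheilion"):
            mouth_opening_series(traj)

    def test_similarity_invariance_explicit_transform(self):
        traj = make_trajectory(heights=np.linspace(5, 40, 30))
        matrix, offset = similarity(np.deg2rad(30), 2.5, (120.0, -40.0))
        moved = traj.transformed(matrix, offset)
        np.testing.assert_allclose(
            mouth_opening_series(traj), mouth_opening_series(moved), atol=1e-9
        )


class TestPogonionLateral:
    def test_zero_on_midline(self):
        traj = make_trajectory(lateral=np.zeros(20))
        np.testing.assert_allclose(pogonion_lateral_series(traj), 0.0)

    def test_one_face_width_displacement(self):
        traj = make_trajectory(lateral=[200.0, 0.0])  # face width is 200
        series = pogonion_lateral_series(traj)
        assert series[0] == pytest.approx(1.0)
        assert series[1] == pytest.approx(0.0)

    def test_mirror_image_invariance(self):
        lateral = np.sin(np.linspace(0, 3, 25)) * 8.0
        traj = make_trajectory(lateral=lateral)
        mirrored = traj.transformed(np.array([[-1.0, 0.0], [0.0, 1.0]]), (0.0, 0.0))
        np.testing.assert_allclose(
            pogonion_lateral_series(traj),
            pogonion_lateral_series(mirrored),
            atol=1e-9,
        )

    def test_degenerate_rest_rejected(self):
        traj = make_trajectory()
        rest = traj.rest.copy()
        for name in ("exocanthion_left", "exocanthion_right"):
            rest[landmark_index(name)] = (0.0, 0.0)
        bad = type(traj)(
            participant_id="P1", word="Ba", coords=traj.coords, rest=rest
        )
        with pytest.raises(KinematicsError, match="degenerate|coincident"):
            pogonion_lateral_series(bad)

    @settings(max_examples=25, derandomize=True)
    @given(
        angle=st.floats(0, 2 * np.pi),
        scale=st.floats(0.1, 10),
        dx=st.floats(-500, 500),
        dy=st.floats(-500, 500),
    )
    def test_similarity_invariance_property(self, angle, scale, dx, dy):
        heights = np.linspace(4, 45, 20)
        lateral = np.cos(np.linspace(0, 2, 20)) * 6.0
        traj = make_trajectory(heights=heights, lateral=lateral)
        moved = traj.transformed(*similarity(angle, scale, (dx, dy)))
        np.testing.assert_allclose(
            mouth_opening_series(traj), mouth_opening_series(moved), rtol=1e-8
        )
        np.testing.assert_allclose(
            pogonion_lateral_series(traj),
            pogonion_lateral_series(moved),
            atol=1e-10,
        )


class TestTimeNormalize:
    def test_constant_series(self):
        out = time_normalize([3.5] * 7)
        assert out.shape == (1000,)
        np.testing.assert_allclose(out, 3.5)

    def test_linear_ramp_preserved(self):
        out = time_normalize(np.linspace(0, 1, 30))
        np.testing.assert_allclose(out, np.linspace(0, 1, 1000), atol=1e-12)

    def test_endpoints_exact(self):
        values = np.array([2.7, -1.0, 9.9, 4.2])
        out = time_normalize(values)
        assert out[0] == values[0] and out[-1] == values[-1]

    def test_sine_against_dense_interpolation_oracle(self):
        t = np.arange(48) / 60.0
        values = np.sin(2 * np.pi * 2.0 * t / t[-1])
        out = time_normalize(values)
        # brute-force oracle: piecewise-linear evaluation at each target point
        src = np.linspace(0, 1, len(values))
        dst = np.linspace(0, 1, 1000)
        oracle = np.empty(1000)
        for i, x in enumerate(dst):
            j = min(np.searchsorted(src, x, side="right"), len(src) - 1)
            x0, x1 = src[j - 1], src[j]
            w = 0.0 if x1 == x0 else (x - x0) / (x1 - x0)
            oracle[i] = values[j - 1] * (1 - w) + values[j] * w
        assert np.max(np.abs(out - oracle)) < 1e-12
        # and the resampled curve tracks the analytic sine to within the
        # piecewise-linear error bound h^2/8 * max|f''| for h = 1/47
        bound = (2 * np.pi * 2.0) ** 2 / (8 * 47**2)
        assert np.max(np.abs(out - np.sin(2 * np.pi * 2.0 * dst))) < bound * 1.05

    def test_idempotence(self):
        values = np.random.default_rng(3).normal(size=200)
        once = time_normalize(values, n=1000)
        np.testing.assert_array_equal(once, time_normalize(once, n=1000))

    def test_too_short_series_rejected(self):
        with pytest.raises(KinematicsError):
            time_normalize([1.0])


class TestDerivative:
    def test_constant_is_zero(self):
        np.testing.assert_allclose(derivative_series(np.full(100, 2.2)), 0.0)

    def test_linear_ramp_constant_slope(self):
        out = derivative_series(np.linspace(0, 3, 1000))
        np.testing.assert_allclose(out, 3.0, atol=1e-9)

    def test_sine_analytic_derivative(self):
        t = np.linspace(0, 1, 1000)
        out = derivative_series(np.sin(2 * np.pi * t))
        assert np.max(np.abs(out - 2 * np.pi * np.cos(2 * np.pi * t))) < 1e-3


class TestSubPeriods:
    def test_index_convention(self):
        segments = extract_subperiods(np.arange(1000.0), [SubPeriodInterval(20, 60)])
        assert segments[0][0] == 200 and segments[0][-1] == 599
        assert len(segments[0]) == 400

    def test_full_interval_is_identity(self):
        values = np.random.default_rng(0).normal(size=1000)
        (segment,) = extract_subperiods(values, [SubPeriodInterval(0, 100)])
        np.testing.assert_array_equal(segment, values)

    def test_papa_has_two_intervals(self):
        for criterion in ("jaw_range", "jaw_control"):
            assert len(SUBPERIOD_INTERVALS[("Papa", criterion)]) == 2
        segments = extract_subperiods(
            np.arange(1000.0), SUBPERIOD_INTERVALS[("Papa", "jaw_range")]
        )
        assert len(segments) == 2

    def test_invalid_interval_rejected(self):
        with pytest.raises(KinematicsError):
            SubPeriodInterval(60, 20)

    def test_packaged_table_covers_all_words(self):
        table = load_interval_table()
        assert set(w for w, _ in table) == set(CANONICAL_WORDS)


class TestRangeOfMotion:
    def test_constant_segment_zero(self):
        assert range_of_motion([1.3, 1.3, 1.3]) == 0.0

    def test_arithmetic(self):
        assert range_of_motion([0.2, 1.7, 0.9]) == pytest.approx(1.5)

    def test_sine_full_period_extremes(self):
        t = np.linspace(0, 1, 1000)
        assert range_of_motion(np.sin(2 * np.pi * t)) == pytest.approx(2.0, abs=1e-4)

    def test_order_invariance_and_interior_points(self):
        rng = np.random.default_rng(1)
        segment = rng.normal(size=50)
        assert range_of_motion(segment) == range_of_motion(np.sort(segment))
        lo, hi = segment.min(), segment.max()
        padded = np.concatenate([segment, rng.uniform(lo, hi, size=20)])
        assert range_of_motion(padded) == range_of_motion(segment)

    def test_empty_segment_rejected(self):
        with pytest.raises(KinematicsError):
            range_of_motion([])


class TestMeasurementSeries:
    def test_velocity_is_derivative_of_normalized_opening(self, toy_trajectory):
        opening = measurement_series(toy_trajectory, "mouth_opening")
        velocity = measurement_series(toy_trajectory, "mouth_opening_velocity")
        np.testing.assert_allclose(velocity, derivative_series(opening))

    def test_unknown_measurement_rejected(self, toy_trajectory):
        with pytest.raises(KinematicsError):
            measurement_series(toy_trajectory, "tongue_height")
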