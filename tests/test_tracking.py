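"""Tracking statistics: unwrapping, endpoint speeds, axis fits, dwells."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rotorratchet import (
    AngularTrajectory,
    SpeedRecord,
    TipPositionSeries,
    angles_from_positions,
    angular_velocity,
    dwell_positions,
    segment_speeds,
    speed_histogram,
    speed_vs_axis,
    turns_per_cycle,
    unwrap,
)
from rotorratchet.tracking import _axis_fit_from_points, robust_slope

TWO_PI = 2.0 * math.pi


def _series_from_angles(angles, fps=250.0):
    n = len(angles)
    return TipPositionSeries(
        frame_index=np.arange(n),
        time_s=np.arange(n) / fps,
        x_nm=275.0 * np.cos(angles),
        y_nm=275.0 * np.sin(angles),
        localization_sigma_nm=0.0,
    )


class TestAngles:
    def test_angles_recovered_from_positions(self):
        truth = np.linspace(-3.0, 3.0, 50)
        series = _series_from_angles(truth)
        ang = angles_from_positions(series)
        np.testing.assert_allclose(ang, truth, atol=1e-12)

    def test_center_coincidence_names_frame(self):
        series = TipPositionSeries(
            frame_index=np.arange(2),
            time_s=np.array([0.0, 0.004]),
            x_nm=np.array([1.0, 0.0]),
            y_nm=np.array([0.0, 0.0]),
        )
        with pytest.raises(ValueError, match="frame 1"):
            angles_from_positions(series)


class TestUnwrap:
    @given(
        st.lists(st.floats(-0.5, 0.5), min_size=2, max_size=200),
        st.floats(-math.pi, math.pi),
    )
    def test_recovers_cumulative_angle_for_small_steps(self, steps, start):
        truth = start + np.concatenate([[0.0], np.cumsum(steps)])
        wrapped = np.mod(truth + math.pi, TWO_PI) - math.pi
        rec = unwrap(wrapped)
        np.testing.assert_allclose(np.diff(rec), np.diff(truth), atol=1e-9)

    def test_unwrap_invariant_under_wrapping(self):
        theta = np.cumsum(np.full(100, 0.8))
        np.testing.assert_allclose(
            np.diff(unwrap(np.mod(theta, TWO_PI))), np.diff(theta), atol=1e-9
        )

    def test_tie_resolved_toward_plus_pi(self):
        rec = unwrap(np.array([0.0, math.pi]))
        assert rec[1] == pytest.approx(math.pi)
        rec = unwrap(np.array([0.5, 0.5 - math.pi]))
        assert rec[1] - rec[0] == pytest.approx(math.pi)

    def test_empty_and_single(self):
        assert unwrap(np.array([])).size == 0
        np.testing.assert_array_equal(unwrap(np.array([1.2])), [1.2])


class TestEndpointVelocity:
    def test_exact_endpoint_formula(self):
        t = np.arange(11) * 0.1
        theta = np.radians(3.0) * t**2  # nonlinear: endpoint, not slope
        traj = AngularTrajectory(t, theta)
        expected = math.degrees((theta[-1] - theta[0]) / (t[-1] - t[0]))
        assert angular_velocity(traj) == pytest.approx(expected, abs=1e-12)

    def test_window_selection(self):
        t = np.arange(11) * 0.1
        traj = AngularTrajectory(t, np.radians(10.0) * t)
        assert angular_velocity(traj, (0.2, 0.5)) == pytest.approx(10.0)
        with pytest.raises(ValueError):
            angular_velocity(traj, (0.5, 0.5))

    def test_sign_convention_ccw_positive(self):
        t = np.arange(100) * 0.004
        ccw = AngularTrajectory(t, 2.0 * t)
        cw = AngularTrajectory(t, -2.0 * t)
        assert angular_velocity(ccw) > 0
        assert angular_velocity(cw) < 0
        assert turns_per_cycle(angular_velocity(ccw), 5.0) > 0

    def test_robust_slope_agrees_on_linear_data(self):
        t = np.arange(50) * 0.01
        traj = AngularTrajectory(t, 1.5 * t)
        assert robust_slope(traj) == pytest.approx(math.degrees(1.5), rel=1e-9)


class TestSpeedHistogram:
    def test_fractions_and_mean(self):
        records = [
            SpeedRecord("a", "s0", 100.0),
            SpeedRecord("a", "s1", 50.0),
            SpeedRecord("b", "s0", -30.0),
            SpeedRecord("b", "s1", 0.0),
        ]
        h = speed_histogram(records)
        assert h["n"] == 4
        assert h["ccw_fraction"] == pytest.approx(0.5)
        assert h["cw_fraction"] == pytest.approx(0.25)
        assert h["mean"] == pytest.approx(30.0)
        assert h["counts"].sum() == 4

    def test_plain_floats_accepted(self):
        h = speed_histogram([10.0, -20.0, 35.0], bin_width=10.0)
        assert h["n"] == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            speed_histogram([])


class TestSegmentSpeeds:
    def test_speeds_from_metadata(self):
        t = np.arange(0, 501) * 0.004
        theta = np.radians(100.0) * t
        traj = AngularTrajectory(
            t,
            theta,
            metadata={
                "segment_boundaries_s": [0.0, 1.0, 2.0],
                "segment_labels": [
                    {"waveform": "square", "period_s": 0.2, "axis_deg": 0.0},
                    {"waveform": "off", "period_s": None, "axis_deg": 0.0},
                ],
            },
        )
        recs = segment_speeds(traj)
        assert len(recs) == 2
        assert recs[0].omega_deg_s == pytest.approx(100.0)
        assert recs[0].frequency_hz == pytest.approx(5.0)
        assert recs[0].turns_per_cycle == pytest.approx(100.0 / 1800.0)
        assert recs[1].frequency_hz is None
        assert math.isnan(recs[1].turns_per_cycle)

    def test_missing_boundaries_rejected(self):
        traj = AngularTrajectory(np.arange(3) * 0.1, np.zeros(3))
        with pytest.raises(ValueError):
            segment_speeds(traj)


class TestAxisFit:
    def test_exact_sinusoid_recovered(self):
        axes = np.arange(0.0, 181.0, 5.0)
        speeds = 300.0 * np.sin(2 * np.radians(axes - 25.0)) + 40.0
        fit = _axis_fit_from_points(axes, speeds, harmonic=2)
        assert fit.amplitude == pytest.approx(300.0, rel=1e-9)
        assert fit.phase_deg == pytest.approx(25.0, abs=1e-9)
        assert fit.offset == pytest.approx(40.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.p_value < 1e-10

    def test_flat_response_not_significant(self):
        rng = np.random.default_rng(0)
        axes = np.arange(0.0, 181.0, 5.0)
        speeds = rng.normal(0.0, 1.0, axes.size)
        fit = _axis_fit_from_points(axes, speeds, harmonic=2)
        assert fit.r_squared < 0.3
        assert fit.p_value > 0.01

    def test_phase_corrected_axes_align_two_motors(self):
        axes = np.arange(0.0, 181.0, 5.0)
        a = _axis_fit_from_points(axes, np.sin(2 * np.radians(axes - 10.0)), 2)
        b = _axis_fit_from_points(axes, np.sin(2 * np.radians(axes - 60.0)), 2)
        pred_a = a.predict(a.phase_corrected_axes() + a.phase_deg)
        pred_b = b.predict(b.phase_corrected_axes() + b.phase_deg)
        # after phase correction both responses are sin(2 phi')
        np.testing.assert_allclose(
            a.predict(a.phase_deg + 45.0), b.predict(b.phase_deg + 45.0), atol=1e-9
        )
        assert pred_a.shape == pred_b.shape

    def test_speed_vs_axis_uses_metadata(self, biased_landscape):
        from rotorratchet import AxisSweep, SimulationConfig, simulate_protocol

        traj = simulate_protocol(
            biased_landscape,
            AxisSweep(stop_deg=60.0),
            SimulationConfig(seed=2),
        )
        fit = speed_vs_axis(traj)
        assert fit.axes_deg.size == 13
        assert np.isfinite(fit.amplitude)

    def test_too_few_segments_rejected(self):
        traj = AngularTrajectory(np.arange(3) * 0.1, np.zeros(3))
        with pytest.raises(ValueError):
            speed_vs_axis(traj, axis_schedule=[(0.0, 0.1, 0.0), (0.1, 0.2, 5.0)])


class TestTurnsPerCycle:
    def test_values_and_nan(self):
        assert turns_per_cycle(360.0, 1.0) == pytest.approx(1.0)
        assert turns_per_cycle(612.0, 5.0) == pytest.approx(0.34)
        assert math.isnan(turns_per_cycle(100.0, 0.0))
        with pytest.raises(ValueError):
            turns_per_cycle(100.0, -1.0)


class TestDwellPositions:
    def test_peaks_of_synthetic_occupancy(self):
        rng = np.random.default_rng(3)
        centers = np.radians([15.0, 75.0, 135.0, 195.0, 255.0, 315.0])
        ang = rng.choice(centers, size=40_000) + rng.normal(0.0, 0.08, 40_000)
        peaks = dwell_positions(ang)
        assert peaks.size == 6
        np.testing.assert_allclose(peaks, np.degrees(centers), atol=3.0)

    def test_circular_peak_at_zero(self):
        rng = np.random.default_rng(4)
        ang = rng.normal(0.0, 0.1, 40_000)  # peak straddles the 0/360 seam
        peaks = dwell_positions(ang)
        assert peaks.size == 1
        assert min(peaks[0], 360.0 - peaks[0]) < 5.0

    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="frames"):
            dwell_positions(np.zeros(100))

    def test_uniform_histogram_has_no_peaks(self):
        ang = np.linspace(0.0, TWO_PI, 20_000, endpoint=False)
        assert dwell_positions(ang).size == 0
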