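"""Langevin integrator: determinism, stability, statistics, protocols, I/O."""

import json
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rotorratchet import (
    AmplitudeSweep,
    AngularTrajectory,
    AxisSweep,
    ConstantDrive,
    FieldProtocol,
    FrequencySweep,
    RotorLandscape,
    SimulationConfig,
    SpringConfig,
    drift_diffusion_trajectory,
    read_trajectory,
    simulate,
    simulate_protocol,
    simulate_with_spring,
    voltage_to_amplitude,
    write_trajectory,
)
from rotorratchet.simulate import build_protocol


class TestDeterminism:
    def test_same_seed_identical(self, biased_landscape, short_drive):
        cfg = SimulationConfig(seed=5)
        a = simulate(biased_landscape, short_drive, cfg)
        b = simulate(biased_landscape, short_drive, cfg)
        np.testing.assert_array_equal(a.theta, b.theta)

    def test_different_seeds_differ(self, biased_landscape, short_drive):
        a = simulate(biased_landscape, short_drive, SimulationConfig(seed=5))
        b = simulate(biased_landscape, short_drive, SimulationConfig(seed=6))
        assert not np.array_equal(a.theta, b.theta)


class TestStability:
    def test_dt_above_bound_rejected(self, biased_landscape, short_drive):
        cfg = SimulationConfig(dt=1e-2)
        with pytest.raises(ValueError, match="stability"):
            simulate(biased_landscape, short_drive, cfg)

    def test_bound_scales_with_curvature(self, biased_landscape):
        stiff = RotorLandscape(well_depth=40.0, well_inverse_width=100.0)
        cfg = SimulationConfig()
        assert cfg.stability_limit(stiff) < cfg.stability_limit(biased_landscape)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(damping=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(dt=-1e-5)
        with pytest.raises(ValueError):
            SimulationConfig(record_stride=0)


class TestTrajectoryContainer:
    def test_uniform_grid_enforced(self):
        with pytest.raises(ValueError):
            AngularTrajectory(np.array([0.0, 0.1, 0.3]), np.zeros(3))

    def test_finite_values_enforced(self):
        with pytest.raises(ValueError):
            AngularTrajectory(np.array([0.0, 0.1]), np.array([0.0, np.nan]))

    def test_crop_rebases_time(self, driven_trajectory):
        sub = driven_trajectory.crop(2.0)
        assert sub.times[0] == 0.0
        assert sub.duration == pytest.approx(driven_trajectory.duration - 2.0)
        i0 = int(round(2.0 / driven_trajectory.dt))
        np.testing.assert_array_equal(sub.theta, driven_trajectory.theta[i0:])

    def test_crop_too_narrow_rejected(self, driven_trajectory):
        with pytest.raises(ValueError):
            driven_trajectory.crop(driven_trajectory.duration)


class TestStatistics:
    def test_free_diffusion_matches_kt_over_damping(self):
        # fluctuation-dissipation: D = kT/damping for a flat landscape
        flat = RotorLandscape(field_strength=0.0, well_depth=0.0)
        protocol = FieldProtocol.constant(4.0, waveform="off")
        sq = []
        for seed in range(20):
            traj = simulate(flat, protocol, SimulationConfig(seed=seed))
            sq.append(np.diff(traj.theta) ** 2)
        sq = np.concatenate(sq)
        dt = 2e-5 * 200
        d_hat = sq.mean() / (2 * dt)
        se = d_hat * math.sqrt(2.0 / sq.size)
        assert d_hat == pytest.approx(10.0, abs=4 * se)

    def test_zero_temperature_rolls_into_well(self, biased_landscape):
        protocol = FieldProtocol.constant(0.5, waveform="off")
        cfg = SimulationConfig(
            seed=0, thermal_energy=0.0, initial_angle=math.radians(60.0)
        )
        traj = simulate(biased_landscape, protocol, cfg)
        assert traj.theta[-1] == pytest.approx(math.radians(45.0), abs=1e-3)
        # monotone descent: no noise, so theta moves one way only
        d = np.diff(traj.theta)
        assert np.all(d <= 1e-12)

    def test_biased_motor_drifts_ccw(self, biased_landscape):
        traj = simulate_protocol(
            biased_landscape,
            ConstantDrive(duration_s=8.0),
            SimulationConfig(seed=3),
        ).crop(2.0)
        omega = math.degrees((traj.theta[-1] - traj.theta[0]) / traj.duration)
        assert omega > 100.0  # strongly counterclockwise

    def test_mirrored_motor_drifts_cw(self, biased_landscape):
        traj = simulate_protocol(
            biased_landscape.mirrored(),
            ConstantDrive(duration_s=8.0),
            SimulationConfig(seed=3),
        ).crop(2.0)
        omega = math.degrees((traj.theta[-1] - traj.theta[0]) / traj.duration)
        assert omega < -100.0


class TestSpring:
    def test_spring_stalls_and_unwinds(self, biased_landscape):
        protocol = FieldProtocol(
            [
                FieldProtocol.constant(4.0, waveform="square", period=0.2).segments[0],
                FieldProtocol.constant(4.0, waveform="off").segments[0],
            ]
        )
        anchor = biased_landscape.minima_offset
        spring = SpringConfig(stiffness=0.5, anchor_angle=anchor)
        winds = []
        for seed in range(6):
            traj = simulate_with_spring(
                biased_landscape,
                protocol,
                SimulationConfig(seed=seed, initial_angle=anchor),
                spring,
            )
            i_mid = int(round(4.0 / traj.dt))
            winds.append(traj.theta[i_mid] - anchor)
        # winding: displaced from the anchor, bounded (stalled, not running)
        assert np.mean(winds) > 0.3
        assert np.mean(winds) < 4.0 * math.pi

    def test_disengaged_spring_equals_plain_dynamics(self, biased_landscape, short_drive):
        cfg = SimulationConfig(seed=9)
        plain = simulate(biased_landscape, short_drive, cfg)
        loose = simulate_with_spring(
            biased_landscape, short_drive, cfg, SpringConfig(stiffness=0.5, engaged=False)
        )
        np.testing.assert_array_equal(plain.theta, loose.theta)


class TestProtocols:
    def test_axis_sweep_segments(self):
        p = build_protocol(AxisSweep())
        assert len(p.segments) == 37  # 0..180 in 5 deg steps
        assert p.segments[0].axis_angle == 0.0
        assert p.segments[-1].axis_angle == pytest.approx(math.pi)
        assert all(s.duration == 1.6 for s in p.segments)

    def test_frequency_sweep_periods(self):
        p = build_protocol(FrequencySweep(frequencies_hz=(10.0, 5.0)))
        assert [s.period for s in p.segments] == [0.1, 0.2]

    def test_amplitude_sweep_zero_volt_is_off(self):
        p = build_protocol(AmplitudeSweep(voltages=(0.0, 20.0, 40.0)))
        assert p.segments[0].waveform == "off"
        assert p.segments[1].amplitude_scale == pytest.approx(1.0)
        assert p.segments[2].amplitude_scale == pytest.approx(2.0)

    def test_voltage_map_is_linear(self):
        assert voltage_to_amplitude(0.0) == 0.0
        assert voltage_to_amplitude(20.0) == 1.0
        assert voltage_to_amplitude(30.0, v_ref=20.0) == pytest.approx(1.5)
        with pytest.raises(ValueError):
            voltage_to_amplitude(-1.0)

    def test_metadata_records_schedule(self, biased_landscape):
        traj = simulate_protocol(
            biased_landscape,
            FrequencySweep(frequencies_hz=(10.0, 5.0), dwell_s=1.0),
            SimulationConfig(seed=0),
        )
        assert traj.metadata["segment_boundaries_s"] == [0.0, 1.0, 2.0]
        assert [s["period_s"] for s in traj.metadata["segment_labels"]] == [0.1, 0.2]
        assert traj.metadata["seed"] == 0


class TestDriftDiffusion:
    @given(st.integers(0, 1000))
    def test_increment_moments(self, seed):
        traj = drift_diffusion_trajectory(2.0, 1.0, 50.0, 0.01, seed=seed)
        d = np.diff(traj.theta)
        assert d.mean() == pytest.approx(0.02, abs=5 * math.sqrt(0.02 / d.size))

    def test_variance_scale(self):
        traj = drift_diffusion_trajectory(0.0, 1.0, 2000.0, 0.01, seed=1)
        d = np.diff(traj.theta)
        assert d.var() == pytest.approx(2 * 1.0 * 0.01, rel=0.02)


class TestTrajectoryIO:
    def test_round_trip(self, tmp_path, driven_trajectory):
        path = tmp_path / "traj.csv"
        write_trajectory(driven_trajectory, path)
        back = read_trajectory(path)
        np.testing.assert_allclose(back.theta, driven_trajectory.theta, atol=1e-12)
        np.testing.assert_allclose(back.times, driven_trajectory.times, atol=1e-15)
        assert back.metadata["seed"] == driven_trajectory.metadata["seed"]

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("time_s,angle\n0.0,1.0\n0.1,2.0\n")
        with pytest.raises(ValueError, match="theta_unwrapped_deg"):
            read_trajectory(path)

    def test_header_units_are_degrees(self, tmp_path):
        path = tmp_path / "traj.csv"
        traj = AngularTrajectory(np.array([0.0, 1.0]), np.array([0.0, math.pi]))
        write_trajectory(traj, path)
        lines = path.read_text().splitlines()
        assert lines[0] == "time_s,theta_unwrapped_deg"
        assert float(lines[2].split(",")[1]) == pytest.approx(180.0)

    def test_sidecar_metadata(self, tmp_path, driven_trajectory):
        path = tmp_path / "traj.csv"
        write_trajectory(driven_trajectory, path)
        meta = json.loads((tmp_path / "traj.csv.meta.json").read_text())
        assert meta["landscape"]["theta0_deg"] == pytest.approx(45.0)
        assert meta["ground_truth"] is True
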