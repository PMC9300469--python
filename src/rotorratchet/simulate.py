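"""Overdamped Langevin dynamics of the rotor in the switching landscape.

The rotor angle obeys ``damping * dtheta/dt = -dU/dtheta + eta(t)`` with
white noise ``<eta(t) eta(t')> = 2 kT damping delta(t - t')``, integrated
with the Euler-Maruyama scheme. Defaults use reduced units (kT = 1,
damping = 1 kT s/rad^2, so the free diffusion coefficient is 1 rad^2/s).

Besides the generic :func:`simulate`, the module provides the experiment
protocols used to characterize the motors (field-axis sweeps, frequency
and amplitude sweeps, DC and field-off controls), the torsional-spring
motor variant, and an exact drift-diffusion generator used as an analysis
reference process.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .landscape import (
    FieldProtocol,
    FieldSegment,
    RotorLandscape,
    field_amplitude_prefactor,
)

__all__ = [
    "SimulationConfig",
    "AngularTrajectory",
    "SpringConfig",
    "AxisSweep",
    "FrequencySweep",
    "AmplitudeSweep",
    "simulate",
    "simulate_with_spring",
    "simulate_protocol",
    "voltage_to_amplitude",
    "drift_diffusion_trajectory",
    "write_trajectory",
    "read_trajectory",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class SimulationConfig:
    """Integrator settings.

    ``damping`` is in kBT*s/rad^2 and ``thermal_energy`` in kBT, so the
    free diffusion coefficient is ``thermal_energy / damping`` (rad^2/s).
    ``dt`` must satisfy the explicit-scheme stability bound
    ``dt < 0.1 * damping / max|U''|`` (checked against the landscape at
    simulation time). A fixed ``seed`` gives bit-identical trajectories.
    """

    damping: float = 0.1
    thermal_energy: float = 1.0
    dt: float = 2e-5
    record_stride: int = 200
    seed: int = 0
    initial_angle: float | None = None

    def __post_init__(self) -> None:
        if self.damping <= 0:
            raise ValueError("damping must be > 0")
        if self.thermal_energy < 0:
            raise ValueError("thermal_energy must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.record_stride < 1 or int(self.record_stride) != self.record_stride:
            raise ValueError("record_stride must be a positive integer")

    def stability_limit(self, landscape: RotorLandscape, kappa: float = 0.0) -> float:
        """Largest admissible dt: 0.1 * damping / max|U''|."""
        curv = (
            2.0 * landscape.well_depth * landscape.well_inverse_width
            + field_amplitude_prefactor(landscape)
            + kappa
        )
        if curv == 0.0:
            return math.inf
        return 0.1 * self.damping / curv

    def check_stability(self, landscape: RotorLandscape, kappa: float = 0.0) -> None:
        limit = self.stability_limit(landscape, kappa)
        if self.dt >= limit:
            raise ValueError(
                f"dt={self.dt:g} violates the stability bound {limit:g} "
                f"(0.1 * damping / max|U''|) for this landscape"
            )


@dataclass(frozen=True)
class SpringConfig:
    """Linear torsional spring at the rotor pivot.

    Adds a restoring torque ``-stiffness * (theta - anchor_angle)`` to the
    drift when ``engaged``; stiffness in kBT/rad^2.
    """

    stiffness: float = 0.5
    anchor_angle: float = 0.0
    engaged: bool = True

    def __post_init__(self) -> None:
        if self.stiffness < 0:
            raise ValueError("stiffness must be >= 0")


@dataclass
class AngularTrajectory:
    """Uniformly sampled unwrapped rotor angle versus time.

    ``theta`` is cumulative (never wrapped); ``times`` is a uniform grid.
    ``metadata`` carries the provenance (config echo, protocol segment
    boundaries, seed, ground-truth flag).
    """

    times: np.ndarray
    theta: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.times.shape != self.theta.shape or self.times.ndim != 1:
            raise ValueError("times and theta must be 1D arrays of equal length")
        if self.times.size < 2:
            raise ValueError("trajectory needs at least two samples")
        steps = np.diff(self.times)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("times must be a uniform grid")
        if steps[0] <= 0:
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.theta))):
            raise ValueError("trajectory contains non-finite values")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return self.times.size

    def crop(self, t_start: float, t_stop: float | None = None) -> "AngularTrajectory":
        """Sub-trajectory on [t_start, t_stop], times rebased to zero.

        Used to discard the initial relaxation transient before computing
        steady-state statistics.
        """
        t1 = self.times[-1] if t_stop is None else float(t_stop)
        i0 = int(np.searchsorted(self.times, t_start - 1e-12))
        i1 = int(np.searchsorted(self.times, t1 + 1e-12))
        if i1 - i0 < 2:
            raise ValueError(f"crop window [{t_start}, {t1}] keeps fewer than two samples")
        meta = dict(self.metadata)
        meta["cropped_from_s"] = float(self.times[i0])
        return AngularTrajectory(
            self.times[i0:i1] - self.times[i0], self.theta[i0:i1], meta
        )


def voltage_to_amplitude(volts: float, v_ref: float = 20.0) -> float:
    """Map an applied voltage to a dimensionless field amplitude scale.

    Linear map V/V_ref; the reference voltage (default 20 V) corresponds
    to amplitude scale 1.
    """
    if volts < 0:
        raise ValueError("volts must be >= 0")
    if v_ref <= 0:
        raise ValueError("v_ref must be > 0")
    return volts / v_ref


def _snap_dt(dt: float, protocol: FieldProtocol) -> float:
    """Shrink dt so the shortest square half-period is an integer number
    of steps (keeps the E(t) sign flips aligned with the step grid)."""
    halves = [
        0.5 * s.period
        for s in protocol.segments
        if s.waveform in ("square", "smoothed_square")
    ]
    if not halves:
        return dt
    h = min(halves)
    k = max(1, math.ceil(h / dt - 1e-9))
    return h / k


def _segment_arrays(protocol: FieldProtocol, landscape: RotorLandscape, dt: float):
    n = len(protocol.segments)
    steps = np.empty(n, dtype=np.int64)
    code = np.empty(n, dtype=np.int64)
    period = np.ones(n, dtype=np.float64)
    pref = np.empty(n, dtype=np.float64)
    axis = np.empty(n, dtype=np.float64)
    order = np.ones(n, dtype=np.int64)
    printed = np.zeros(n, dtype=np.bool_)
    a4pi = field_amplitude_prefactor(landscape)
    for i, seg in enumerate(protocol.segments):
        steps[i] = max(1, round(seg.duration / dt))
        code[i] = seg.waveform_code
        if seg.period is not None:
            period[i] = seg.period
        pref[i] = a4pi * seg.amplitude_scale
        axis[i] = seg.axis_angle
        if seg.fourier_order is not None:
            order[i] = seg.fourier_order
        printed[i] = seg.dialect == "printed"
    return steps, code, period, pref, axis, order, printed


def _run(
    landscape: RotorLandscape,
    protocol: FieldProtocol,
    config: SimulationConfig,
    kappa: float = 0.0,
    anchor: float = 0.0,
) -> AngularTrajectory:
    config.check_stability(landscape, kappa)
    dt = _snap_dt(config.dt, protocol)
    seg = _segment_arrays(protocol, landscape, dt)
    total_steps = int(seg[0].sum())
    rng = np.random.default_rng(config.seed)
    if config.thermal_energy > 0:
        noise = rng.standard_normal(total_steps)
        noise_amp = math.sqrt(2.0 * config.thermal_energy * dt / config.damping)
    else:
        noise = np.zeros(total_steps)
        noise_amp = 0.0
    theta_init = (
        config.initial_angle
        if config.initial_angle is not None
        else landscape.minima_offset
    )
    theta_rec, fail = _kernels.integrate(
        theta_init,
        dt,
        config.damping,
        noise_amp,
        *seg,
        landscape.well_depth,
        landscape.well_inverse_width,
        landscape.minima_offset,
        landscape.minima_spacing,
        landscape.n_images,
        kappa,
        anchor,
        noise,
        config.record_stride,
    )
    if fail >= 0:
        raise RuntimeError(f"integration diverged (non-finite angle) at step {fail}")
    times = np.arange(theta_rec.size) * (dt * config.record_stride)
    meta = {
        "dt_effective": dt,
        "seed": config.seed,
        "ground_truth": True,
        "segment_boundaries_s": protocol.segment_boundaries().tolist(),
        "segment_labels": [
            {
                "waveform": s.waveform,
                "period_s": s.period,
                "amplitude_scale": s.amplitude_scale,
                "axis_deg": math.degrees(s.axis_angle),
            }
            for s in protocol.segments
        ],
        "config": {
            "damping": config.damping,
            "thermal_energy": config.thermal_energy,
            "dt": config.dt,
            "record_stride": config.record_stride,
            "initial_angle": theta_init,
        },
        "landscape": {
            "a_kT": landscape.field_strength,
            "b_kT": landscape.well_depth,
            "c_per_rad2": landscape.well_inverse_width,
            "theta0_deg": math.degrees(landscape.minima_offset),
            "n_minima": landscape.n_minima,
        },
    }
    if kappa > 0.0:
        meta["spring"] = {"stiffness_kT_per_rad2": kappa, "anchor_rad": anchor}
    return AngularTrajectory(times, theta_rec, meta)


def simulate(
    landscape: RotorLandscape,
    protocol: FieldProtocol,
    config: SimulationConfig,
) -> AngularTrajectory:
    """Integrate the overdamped Langevin equation in the given landscape.

    Euler-Maruyama update: ``theta += -(dU/dtheta / damping) * dt +
    sqrt(2 kT dt / damping) * xi`` with i.i.d. standard normal ``xi`` from
    the seeded generator. The returned angle is never wrapped.
    """
    return _run(landscape, protocol, config)


def simulate_with_spring(
    landscape: RotorLandscape,
    protocol: FieldProtocol,
    config: SimulationConfig,
    spring: SpringConfig,
) -> AngularTrajectory:
    """Langevin dynamics with an additional linear torsional spring.

    With the field on, the motor winds the spring until the restoring
    torque balances the motor torque (stall); with the field off the
    stored torque unwinds the rotor in the opposite direction.
    """
    kappa = spring.stiffness if spring.engaged else 0.0
    return _run(landscape, protocol, config, kappa=kappa, anchor=spring.anchor_angle)


# --------------------------------------------------------------------------
# experiment protocols


@dataclass(frozen=True)
class AxisSweep:
    """Stepwise rotation of the AC field axis (default 5 deg every 1.6 s)."""

    step_deg: float = 5.0
    dwell_s: float = 1.6
    start_deg: float = 0.0
    stop_deg: float = 180.0
    frequency_hz: float = 5.0
    amplitude_scale: float = 1.0


@dataclass(frozen=True)
class FrequencySweep:
    """Sequence of AC frequencies, each held for ``dwell_s``."""

    frequencies_hz: tuple[float, ...] = (100.0, 10.0, 5.0, 1.0)
    dwell_s: float = 8.0
    axis_deg: float = 0.0
    amplitude_scale: float = 1.0


@dataclass(frozen=True)
class AmplitudeSweep:
    """Sequence of field amplitudes given as voltages (V/V_ref scaling)."""

    voltages: tuple[float, ...] = (0.0, 10.0, 20.0, 40.0, 60.0)
    v_ref: float = 20.0
    dwell_s: float = 8.0
    frequency_hz: float = 5.0
    axis_deg: float = 0.0


@dataclass(frozen=True)
class ConstantDrive:
    """Single-segment drive: 'square', 'dc' or 'off'."""

    waveform: str = "square"
    duration_s: float = 40.0
    frequency_hz: float = 5.0
    axis_deg: float = 0.0
    amplitude_scale: float = 1.0


def build_protocol(spec) -> FieldProtocol:
    """Build the FieldProtocol for a sweep spec or 'dc'/'off' string."""
    if isinstance(spec, str):
        spec = ConstantDrive(waveform=spec)
    if isinstance(spec, ConstantDrive):
        if spec.waveform in ("dc", "off"):
            return FieldProtocol.constant(
                spec.duration_s,
                waveform=spec.waveform,
                axis_angle=math.radians(spec.axis_deg),
                amplitude_scale=spec.amplitude_scale,
            )
        return FieldProtocol.constant(
            spec.duration_s,
            waveform=spec.waveform,
            period=1.0 / spec.frequency_hz,
            axis_angle=math.radians(spec.axis_deg),
            amplitude_scale=spec.amplitude_scale,
        )
    if isinstance(spec, AxisSweep):
        axes = np.arange(spec.start_deg, spec.stop_deg + 0.5 * spec.step_deg, spec.step_deg)
        if axes.size == 0:
            raise ValueError("empty axis sweep")
        return FieldProtocol(
            [
                FieldSegment(
                    duration=spec.dwell_s,
                    waveform="square",
                    period=1.0 / spec.frequency_hz,
                    amplitude_scale=spec.amplitude_scale,
                    axis_angle=math.radians(ax),
                )
                for ax in axes
            ]
        )
    if isinstance(spec, FrequencySweep):
        if not spec.frequencies_hz:
            raise ValueError("empty frequency sweep")
        return FieldProtocol(
            [
                FieldSegment(
                    duration=spec.dwell_s,
                    waveform="square",
                    period=1.0 / f,
                    amplitude_scale=spec.amplitude_scale,
                    axis_angle=math.radians(spec.axis_deg),
                )
                for f in spec.frequencies_hz
            ]
        )
    if isinstance(spec, AmplitudeSweep):
        if not spec.voltages:
            raise ValueError("empty amplitude sweep")
        segs = []
        for v in spec.voltages:
            scale = voltage_to_amplitude(v, spec.v_ref)
            if scale == 0.0:
                segs.append(FieldSegment(duration=spec.dwell_s, waveform="off"))
            else:
                segs.append(
                    FieldSegment(
                        duration=spec.dwell_s,
                        waveform="square",
                        period=1.0 / spec.frequency_hz,
                        amplitude_scale=scale,
                        axis_angle=math.radians(spec.axis_deg),
                    )
                )
        return FieldProtocol(segs)
    raise TypeError(f"unknown sweep spec {spec!r}")


def simulate_protocol(
    landscape: RotorLandscape,
    sweep_spec,
    config: SimulationConfig,
) -> AngularTrajectory:
    """Run one of the standard experiment protocols.

    ``sweep_spec`` is an :class:`AxisSweep`, :class:`FrequencySweep`,
    :class:`AmplitudeSweep`, :class:`ConstantDrive`, or one of the strings
    'dc' / 'off' / 'square'. Segment boundaries are recorded in the
    trajectory metadata for per-segment analysis.
    """
    protocol = build_protocol(sweep_spec)
    return simulate(landscape, protocol, config)


# --------------------------------------------------------------------------
# reference process and I/O


def drift_diffusion_trajectory(
    omega: float,
    diffusion: float,
    duration: float,
    dt: float,
    seed: int = 0,
    theta_init: float = 0.0,
) -> AngularTrajectory:
    """Exact drift-diffusion (constant torque, flat landscape) trajectory.

    Increments are drawn from the exact Gaussian propagator
    ``N(omega*dt, 2*D*dt)`` per step, so the process has no discretization
    bias; used as the closed-form reference for the irreversibility
    estimators.
    """
    if dt <= 0 or duration <= 0:
        raise ValueError("duration and dt must be > 0")
    n = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    steps = omega * dt + math.sqrt(2.0 * diffusion * dt) * rng.standard_normal(n)
    theta = np.concatenate([[theta_init], theta_init + np.cumsum(steps)])
    times = np.arange(n + 1) * dt
    meta = {
        "ground_truth": True,
        "process": "drift_diffusion",
        "omega_rad_s": omega,
        "diffusion_rad2_s": diffusion,
        "seed": seed,
    }
    return AngularTrajectory(times, theta, meta)


def write_trajectory(traj: AngularTrajectory, path: str | Path) -> None:
    """CSV columns time_s, theta_unwrapped_deg; metadata sidecar JSON."""
    path = Path(path)
    df = pd.DataFrame(
        {"time_s": traj.times, "theta_unwrapped_deg": np.degrees(traj.theta)}
    )
    df.to_csv(path, index=False)
    with open(str(path) + ".meta.json", "w") as fh:
        json.dump(traj.metadata, fh, indent=2, default=float)


def read_trajectory(path: str | Path) -> AngularTrajectory:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("time_s", "theta_unwrapped_deg"):
        if col not in df.columns:
            raise ValueError(f"trajectory file {path} missing column {col!r}")
    meta_path = Path(str(path) + ".meta.json")
    meta = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    return AngularTrajectory(
        df["time_s"].to_numpy(), np.radians(df["theta_unwrapped_deg"].to_numpy()), meta
    )
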