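"""Study-level experiment routines.

Each function runs one self-contained numerical experiment at the frozen
study conditions (two-well motor, a = b = 4 kBT, c = 10 rad^-2,
damping 0.1 kBT*s/rad^2 -> free diffusion 10 rad^2/s, 5 Hz square drive)
and returns plain dictionaries of summary statistics. They are shared by
the test suite and the standalone acceptance script so both report the
same quantities.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.stats

from .landscape import FieldProtocol, RotorLandscape, intrinsic_potential
from .simulate import (
    ConstantDrive,
    SimulationConfig,
    SpringConfig,
    drift_diffusion_trajectory,
    simulate,
    simulate_protocol,
    simulate_with_spring,
)
from .thermo import (
    effective_coefficients,
    entropy_production,
    msd_crossover,
    renormalize_slopes,
)
from .tracking import angular_velocity

__all__ = [
    "collapse_experiment",
    "boltzmann_check",
    "free_diffusion_check",
    "drift_diffusion_oracle",
    "drift_null",
    "spring_reversal",
    "efficiency_maximum",
]

DEFAULT_LANDSCAPE = RotorLandscape(minima_offset=math.radians(45.0))
DRIVE_PERIOD_S = 0.2
TRANSIENT_CYCLES = 10


def _spawn_seeds(seed: int, n: int, tag: int) -> list[int]:
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(tag,))
    return [int(s % 2**31) for s in ss.generate_state(n, dtype=np.uint64)]


def collapse_experiment(
    seed: int = 1,
    n_motors: int = 20,
    n_cycles: int = 220,
    lags: tuple[int, ...] = (2, 4, 6),
    theta0_deg: float = 45.0,
) -> dict:
    """Entropy-production collapse over an ensemble of driven motors.

    Simulates ``n_motors`` independent two-well motors at the given well
    offset for ``n_cycles`` field cycles each, computes the
    entropy-production curves at stroboscopic lags, renormalizes each
    motor by its own linear trend, and pools the collapsed slopes.
    """
    landscape = RotorLandscape(minima_offset=math.radians(theta0_deg))
    duration = (n_cycles + TRANSIENT_CYCLES) * DRIVE_PERIOD_S
    curves = []
    for i, s in enumerate(_spawn_seeds(seed, n_motors, tag=0)):
        traj = simulate_protocol(
            landscape,
            ConstantDrive(duration_s=duration),
            SimulationConfig(seed=s),
        ).crop(TRANSIENT_CYCLES * DRIVE_PERIOD_S)
        curves.append(
            entropy_production(
                traj, DRIVE_PERIOD_S, lags, bootstrap_seed=s, label=f"motor{i}"
            )
        )
    ens = renormalize_slopes(curves)
    return {
        "pooled_slope": ens.pooled_slope,
        "per_motor_slopes": [c.slope for c in curves],
        "omega_eff_deg_s": [c.omega_eff_deg_s for c in curves],
        "d_eff_deg2_s": [c.d_eff_deg2_s for c in curves],
        "n_excluded": len(ens.excluded),
        "n_low_confidence": sum(c.low_confidence for c in curves),
        "n_motors": n_motors,
        "n_cycles": n_cycles,
    }


def boltzmann_check(
    seed: int = 1,
    n_walkers: int = 60,
    duration_s: float = 24.0,
    burn_in_s: float = 8.0,
    sample_every_s: float = 2.0,
    n_bins: int = 36,
    landscape: RotorLandscape | None = None,
) -> dict:
    """Field-off equilibrium test: angle histogram against exp(-U/kBT).

    Samples are taken every ``sample_every_s`` (several well relaxation
    times apart) from independent walkers after a burn-in, so they are
    approximately independent; compared to the Boltzmann weights by a
    chi-squared test.
    """
    landscape = landscape or DEFAULT_LANDSCAPE
    protocol = FieldProtocol.constant(duration_s, waveform="off")
    samples = []
    rng = np.random.default_rng(seed)
    for s in _spawn_seeds(seed, n_walkers, tag=1):
        cfg = SimulationConfig(seed=s, initial_angle=rng.uniform(0.0, 2.0 * math.pi))
        traj = simulate(landscape, protocol, cfg)
        keep = traj.times >= burn_in_s
        stride = max(1, int(round(sample_every_s / traj.dt)))
        samples.append(np.mod(traj.theta[keep][::stride], 2.0 * math.pi))
    ang = np.concatenate(samples)
    counts, edges = np.histogram(ang, bins=n_bins, range=(0.0, 2.0 * math.pi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    # expected weights: trapezoid-average of exp(-U) across each bin
    fine = np.linspace(0.0, 2.0 * math.pi, 20 * n_bins + 1)
    w = np.exp(-intrinsic_potential(fine, landscape))
    bin_of = np.clip((fine[:-1] / (2.0 * math.pi) * n_bins).astype(int), 0, n_bins - 1)
    trap = 0.5 * (w[:-1] + w[1:])
    expected = np.bincount(bin_of, weights=trap, minlength=n_bins)
    expected *= counts.sum() / expected.sum()
    chi2, p = scipy.stats.chisquare(counts, expected)
    return {
        "chi2": float(chi2),
        "p_value": float(p),
        "n_samples": int(ang.size),
        "n_bins": n_bins,
        "counts": counts,
        "expected": expected,
        "centers_rad": centers,
    }


def free_diffusion_check(
    seed: int = 1,
    n_seeds: int = 200,
    duration_s: float = 2.0,
    config: SimulationConfig | None = None,
) -> dict:
    """Fluctuation-dissipation check: fitted D against kBT/damping.

    Runs free rotors (flat landscape, field off) and estimates D from the
    mean squared frame-to-frame increment pooled over all seeds; the
    standard error follows from the chi-squared statistics of the
    increments.
    """
    base = config or SimulationConfig()
    landscape = RotorLandscape(field_strength=0.0, well_depth=0.0)
    protocol = FieldProtocol.constant(duration_s, waveform="off")
    sq = []
    dt = None
    for s in _spawn_seeds(seed, n_seeds, tag=2):
        cfg = SimulationConfig(
            damping=base.damping,
            thermal_energy=base.thermal_energy,
            dt=base.dt,
            record_stride=base.record_stride,
            seed=s,
            initial_angle=0.0,
        )
        traj = simulate(landscape, protocol, cfg)
        dt = traj.dt
        sq.append(np.diff(traj.theta) ** 2)
    sq = np.concatenate(sq)
    d_hat = float(sq.mean() / (2.0 * dt))
    # var(x^2) = 2 (2 D dt)^2 for centered Gaussian increments
    se = float(d_hat * math.sqrt(2.0 / sq.size))
    return {
        "d_est_rad2_s": d_hat,
        "d_se_rad2_s": se,
        "d_expected_rad2_s": base.thermal_energy / base.damping,
        "n_increments": int(sq.size),
        "n_seeds": n_seeds,
    }


def drift_diffusion_oracle(
    seed: int = 1,
    omega_rad_s: float = 2.0,
    diffusion_rad2_s: float = 1.0,
    n_frames: int = 1_000_000,
    frame_dt_s: float = 0.05,
    period_s: float = 0.1,
    lags: tuple[int, ...] = (2, 4, 6),
) -> dict:
    """Closed-form oracle: estimators applied to exact drift-diffusion.

    The fluctuation relation gives entropy slope omega/D exactly for this
    process; the effective coefficients and the MSD crossover time
    tc = 2 D / omega^2 are also known in closed form.
    """
    traj = drift_diffusion_trajectory(
        omega_rad_s, diffusion_rad2_s, n_frames * frame_dt_s, frame_dt_s, seed=seed
    )
    curve = entropy_production(traj, period_s, lags, bootstrap_seed=seed)
    omega_deg = math.degrees(omega_rad_s)
    d_deg2 = math.degrees(math.degrees(diffusion_rad2_s))
    omega_est, d_est = effective_coefficients(traj, period_s, lags)
    fit = msd_crossover(traj)
    return {
        "slope_per_deg": curve.slope,
        "slope_expected_per_deg": omega_deg / d_deg2,
        "slope_ratio": curve.slope / (omega_deg / d_deg2),
        "omega_eff_deg_s": omega_est,
        "omega_expected_deg_s": omega_deg,
        "d_eff_deg2_s": d_est,
        "d_expected_deg2_s": d_deg2,
        "msd_tc_s": fit.crossover_time_s,
        "msd_tc_expected_s": 2.0 * diffusion_rad2_s / omega_rad_s**2,
        "n_frames": n_frames,
    }


def drift_null(
    condition: str,
    seed: int = 1,
    n_seeds: int = 12,
    duration_s: float = 24.0,
) -> dict:
    """Symmetry-null drift measurement for one control condition.

    ``condition`` is one of:

    * ``"axis0"``: motor wells at 0 deg (field axis passes through the
      wells; reflection symmetry forbids net drift);
    * ``"dc"``: static field (equilibrium; no drive cycle);
    * ``"highfreq"``: drive period far below the well relaxation time, so
      the rotor only feels the time-averaged (symmetric) landscape.

    Returns the ensemble mean drift, its standard error, and the z-score.
    """
    if condition == "axis0":
        landscape = RotorLandscape(minima_offset=0.0)
        drive = ConstantDrive(duration_s=duration_s)
    elif condition == "dc":
        landscape = DEFAULT_LANDSCAPE
        drive = ConstantDrive(waveform="dc", duration_s=duration_s)
    elif condition == "highfreq":
        landscape = DEFAULT_LANDSCAPE
        # well relaxation time damping/U''(min) ~ 1.25 ms; period 100x shorter
        drive = ConstantDrive(duration_s=duration_s, frequency_hz=80_000.0)
    else:
        raise ValueError(f"unknown null condition {condition!r}")
    drifts = []
    for s in _spawn_seeds(seed, n_seeds, tag=3):
        traj = simulate_protocol(landscape, drive, SimulationConfig(seed=s))
        traj = traj.crop(TRANSIENT_CYCLES * DRIVE_PERIOD_S)
        drifts.append(angular_velocity(traj))
    drifts = np.asarray(drifts)
    mean = float(drifts.mean())
    se = float(drifts.std(ddof=1) / math.sqrt(n_seeds))
    return {
        "condition": condition,
        "mean_drift_deg_s": mean,
        "se_deg_s": se,
        "z_score": mean / se if se > 0 else 0.0,
        "n_seeds": n_seeds,
    }


def spring_reversal(
    seed: int = 1,
    n_seeds: int = 50,
    stiffness: float = 0.5,
    phase_s: float = 4.0,
    n_switch_cycles: int = 8,
) -> dict:
    """Torsional-spring wind-up / release experiment.

    With the AC field on, the motor winds the spring away from its anchor
    until the restoring torque stalls it; switching the field off releases
    the stored torque and the rotor unwinds in the opposite direction. The
    field is toggled on/off repeatedly (as in the experiment) and the mean
    velocity of each phase type is averaged over the switching cycles; a
    single phase endpoint is dominated by the thermal stall fluctuation
    sqrt(kBT/stiffness). Reports the fraction of seeds in which the two
    phase-mean velocities have opposite signs.
    """
    landscape = DEFAULT_LANDSCAPE
    anchor = landscape.minima_offset
    on = FieldProtocol.constant(
        phase_s, waveform="square", period=DRIVE_PERIOD_S
    ).segments[0]
    off = FieldProtocol.constant(phase_s, waveform="off").segments[0]
    protocol = FieldProtocol([on, off] * n_switch_cycles)
    spring = SpringConfig(stiffness=stiffness, anchor_angle=anchor)
    opposite = 0
    wind = []
    unwind = []
    for s in _spawn_seeds(seed, n_seeds, tag=4):
        traj = simulate_with_spring(
            landscape, protocol, SimulationConfig(seed=s, initial_angle=anchor), spring
        )
        v_on = np.mean(
            [
                angular_velocity(traj, (2 * k * phase_s, (2 * k + 1) * phase_s))
                for k in range(n_switch_cycles)
            ]
        )
        v_off = np.mean(
            [
                angular_velocity(traj, ((2 * k + 1) * phase_s, (2 * k + 2) * phase_s))
                for k in range(n_switch_cycles)
            ]
        )
        wind.append(v_on)
        unwind.append(v_off)
        if v_on * v_off < 0:
            opposite += 1
    return {
        "fraction_opposite": opposite / n_seeds,
        "mean_wind_deg_s": float(np.mean(wind)),
        "mean_unwind_deg_s": float(np.mean(unwind)),
        "n_seeds": n_seeds,
        "n_switch_cycles": n_switch_cycles,
    }


def efficiency_maximum(
    zeta_r: float = 4e-22,
    omega_eff: float = 25.0,
    zeta_eff: float = 4e-21,
    n_grid: int = 2_000_001,
) -> dict:
    """Brute-force maximization of the load-line efficiency.

    epsilon(tau) = (omega_eff - tau/zeta_r) * tau / (zeta_eff * omega_eff^2)
    scanned on a dense torque grid, then polished by golden-section search;
    the analytic maximum sits at tau* = zeta_r*omega_eff/2 with
    epsilon_max = zeta_r / (4 zeta_eff).
    """
    import scipy.optimize

    taus = np.linspace(0.0, zeta_r * omega_eff, n_grid)
    eps = (omega_eff - taus / zeta_r) * taus / (zeta_eff * omega_eff**2)
    k = int(np.argmax(eps))
    lo = taus[max(k - 1, 0)]
    hi = taus[min(k + 1, n_grid - 1)]
    res = scipy.optimize.minimize_scalar(
        lambda t: -(omega_eff - t / zeta_r) * t / (zeta_eff * omega_eff**2),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-30},
    )
    tau_star = float(res.x)
    eps_max = float(-res.fun)
    return {
        "tau_star": tau_star,
        "tau_star_expected": zeta_r * omega_eff / 2.0,
        "eps_max": eps_max,
        "eps_max_expected": zeta_r / (4.0 * zeta_eff),
    }
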