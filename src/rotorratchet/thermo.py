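"""Stochastic-thermodynamics irreversibility analysis.

From a single unwrapped trajectory sampled at multiples of the AC field
period T, the entropy production per displacement is estimated as

    ds/kB(dtheta) = < ln[ p(theta0, dtheta) / p(theta0 + dtheta, -dtheta) ] >_theta0

with p the kernel-density estimate of the joint distribution of
(theta0 mod 360, dtheta) over all jump pairs at lag n*T, and the average
taken uniformly over a theta0 grid in [0, 360). For a biased motor the
curve is linear with slope omega_eff/D_eff (1/deg) and independent of the
lag n; renormalizing each motor's curve by its own slope collapses an
ensemble onto the unit-slope line.

All angles at this interface are degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .simulate import AngularTrajectory

__all__ = [
    "JumpDistribution",
    "EntropyProductionCurve",
    "CollapsedEnsemble",
    "MsdFit",
    "jump_pairs",
    "transition_density",
    "entropy_production",
    "renormalize_slopes",
    "effective_coefficients",
    "drift_bootstrap_ci",
    "msd_crossover",
]


# --------------------------------------------------------------------------
# jump pairs and transition densities


@dataclass
class JumpDistribution:
    """All jump pairs (theta0 mod 360, dtheta) at one stroboscopic lag."""

    lag_n: int
    period_s: float
    theta0_deg: np.ndarray       # initial angle mod 360, degrees
    dtheta_deg: np.ndarray       # displacement, unreduced, degrees
    bandwidths_deg: tuple[float, float] | None = None

    @property
    def lag_s(self) -> float:
        return self.lag_n * self.period_s

    @property
    def n_pairs(self) -> int:
        return self.theta0_deg.size


def jump_pairs(traj: AngularTrajectory, n: int, period_s: float) -> JumpDistribution:
    """All overlapping pairs (theta_t, theta_{t+n*T} - theta_t).

    The lag n*T must be an integer multiple of the sampling interval and
    must not exceed the trajectory span.
    """
    if n < 1:
        raise ValueError("lag multiple n must be >= 1")
    lag_s = n * period_s
    ratio = lag_s / traj.dt
    lag_frames = int(round(ratio))
    if abs(ratio - lag_frames) > 1e-6 or lag_frames < 1:
        raise ValueError(
            f"lag {lag_s:g} s is not an integer multiple of the sampling "
            f"interval {traj.dt:g} s"
        )
    if lag_frames >= traj.theta.size:
        raise ValueError("lag exceeds the trajectory span")
    theta_deg = np.degrees(traj.theta)
    theta0 = np.mod(theta_deg[:-lag_frames], 360.0)
    dtheta = theta_deg[lag_frames:] - theta_deg[:-lag_frames]
    return JumpDistribution(lag_n=n, period_s=period_s, theta0_deg=theta0, dtheta_deg=dtheta)


class TransitionDensity:
    """2D Gaussian-kernel density of (theta0 mod 360, dtheta), periodic in theta0.

    Periodicity is implemented by replicating the sample at theta0 +/- 360;
    bandwidths follow Silverman's rule per dimension on the un-replicated
    sample (h = sigma * n^(-1/6) for two dimensions) unless overridden.
    """

    def __init__(
        self,
        jumps: JumpDistribution,
        bandwidths_deg: tuple[float, float] | None = None,
        max_pairs: int = 100_000,
        bandwidth_scale: float = 1.0,
    ):
        if bandwidth_scale <= 0:
            raise ValueError("bandwidth_scale must be > 0")
        if jumps.n_pairs < 100:
            raise ValueError("transition density needs >= 100 pairs")
        t0 = jumps.theta0_deg
        dt = jumps.dtheta_deg
        if t0.size > max_pairs:  # deterministic stride thinning
            stride = int(math.ceil(t0.size / max_pairs))
            t0, dt = t0[::stride], dt[::stride]
        if np.ptp(t0) == 0 and np.ptp(dt) == 0:
            raise ValueError("degenerate jump distribution (all pairs identical)")
        n = t0.size
        if bandwidths_deg is None:
            factor = n ** (-1.0 / 6.0)
            h0 = max(float(np.std(t0)) * factor, 1e-6)
            h1 = max(float(np.std(dt)) * factor, 1e-6)
            bandwidths_deg = (h0, h1)
        self.bandwidths_deg = (
            bandwidths_deg[0] * bandwidth_scale,
            bandwidths_deg[1] * bandwidth_scale,
        )
        self.n_samples = n
        # replicate for periodicity in theta0
        self._x = np.concatenate([t0 - 360.0, t0, t0 + 360.0])
        self._y = np.tile(dt, 3)

    def __call__(self, theta0_deg, dtheta_deg) -> np.ndarray:
        """Density at the given query points (broadcast 1D arrays)."""
        q0 = np.atleast_1d(np.asarray(theta0_deg, dtype=float))
        q1 = np.atleast_1d(np.asarray(dtheta_deg, dtype=float))
        h0, h1 = self.bandwidths_deg
        out = np.empty(q0.size)
        chunk = max(1, int(4e6 // max(self._x.size, 1)) )
        for s in range(0, q0.size, chunk):
            e = min(s + chunk, q0.size)
            z0 = (q0[s:e, None] - self._x[None, :]) / h0
            z1 = (q1[s:e, None] - self._y[None, :]) / h1
            out[s:e] = np.exp(-0.5 * (z0 * z0 + z1 * z1)).sum(axis=1)
        out /= self.n_samples * 2.0 * math.pi * h0 * h1
        return out


def transition_density(
    jumps: JumpDistribution,
    bandwidths_deg: tuple[float, float] | None = None,
    max_pairs: int = 100_000,
    bandwidth_scale: float = 1.0,
) -> TransitionDensity:
    """Gaussian KDE of p(theta0 mod 360, dtheta); see TransitionDensity.

    ``bandwidth_scale`` multiplies both bandwidths (0.5x / 2x sensitivity
    checks of the Silverman default).
    """
    return TransitionDensity(jumps, bandwidths_deg, max_pairs, bandwidth_scale)


# --------------------------------------------------------------------------
# entropy production


@dataclass
class EntropyProductionCurve:
    """ds/kB versus displacement at stroboscopic lags, with fitted slopes."""

    lags: tuple[int, ...]
    dtheta_grid_deg: np.ndarray
    ds_kb: np.ndarray                 # shape (n_lags, n_grid); NaN where floored
    slopes_per_deg: np.ndarray        # through-origin slope per lag
    slope: float                      # pooled slope over all lags
    omega_eff_deg_s: float
    d_eff_deg2_s: float
    drift_ci_deg_s: tuple[float, float]   # block-bootstrap 95% CI of omega_eff
    n_pairs: tuple[int, ...]
    low_confidence: bool
    label: str = ""

    @property
    def biased(self) -> bool:
        """True when the drift is distinguishable from zero (95% CI)."""
        lo, hi = self.drift_ci_deg_s
        return lo > 0.0 or hi < 0.0


def _through_origin_slope(x: np.ndarray, y: np.ndarray) -> float:
    m = np.isfinite(y) & (x != 0)
    if m.sum() < 2:
        return math.nan
    return float((y[m] @ x[m]) / (x[m] @ x[m]))


def drift_bootstrap_ci(
    traj: AngularTrajectory,
    period_s: float,
    n_boot: int = 100,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Block-bootstrap CI of the stroboscopic drift (deg/s).

    Non-overlapping stroboscopic increments at lag T are resampled in
    blocks of 10 to respect residual correlation.
    """
    d = jump_pairs(traj, 1, period_s)
    lag_frames = int(round(period_s / traj.dt))
    steps = d.dtheta_deg[::lag_frames]  # non-overlapping increments
    block = 10
    nb = steps.size // block
    if nb < 2:
        raise ValueError("trajectory too short for the drift bootstrap")
    blocks = steps[: nb * block].reshape(nb, block)
    rng = np.random.default_rng(seed)
    means = blocks[rng.integers(0, nb, size=(n_boot, nb))].mean(axis=(1, 2))
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo) / period_s, float(hi) / period_s


def effective_coefficients(
    traj: AngularTrajectory,
    period_s: float,
    lags: tuple[int, ...] = (2, 4, 6),
) -> tuple[float, float]:
    """(omega_eff, D_eff) in deg/s and deg^2/s from stroboscopic sampling.

    omega_eff is the mean displacement over one field period divided by T;
    D_eff is the weighted through-origin fit of var(dtheta at lag nT)
    against 2nT over the given lags (weights = number of non-overlapping
    pairs at each lag). Stroboscopic sampling removes the deterministic
    intra-cycle motion.
    """
    span = traj.times[-1] - traj.times[0]
    if span < 100 * period_s:
        raise ValueError("effective coefficients need >= 100 field cycles")
    d1 = jump_pairs(traj, 1, period_s)
    omega = float(np.mean(d1.dtheta_deg)) / period_s
    xs, ys, ws = [], [], []
    for n in lags:
        d = jump_pairs(traj, n, period_s)
        ys.append(float(np.var(d.dtheta_deg)))
        xs.append(2.0 * n * period_s)
        ws.append(d.n_pairs / n)  # ~ effective number of independent pairs
    xs, ys, ws = np.array(xs), np.array(ys), np.array(ws)
    d_eff = float((ws * ys * xs).sum() / (ws * xs * xs).sum())
    return omega, d_eff


def entropy_production(
    traj: AngularTrajectory,
    period_s: float,
    lags: tuple[int, ...] = (2, 4, 6),
    dtheta_grid_deg: np.ndarray | None = None,
    theta0_grid_points: int = 36,
    bandwidths_deg: tuple[float, float] | None = None,
    max_pairs: int = 100_000,
    density_floor: float = 1e-12,
    bootstrap_seed: int = 0,
    label: str = "",
    bandwidth_scale: float = 1.0,
) -> EntropyProductionCurve:
    """Estimate ds/kB versus displacement at stroboscopic lags.

    For each lag n, the forward density p(theta0, dtheta) and backward
    density p((theta0 + dtheta) mod 360, -dtheta) are evaluated on a
    uniform theta0 grid and a symmetric dtheta grid; the log-ratio is
    averaged over theta0 (unweighted) and antisymmetrized in dtheta.
    Grid cells where either density falls below ``density_floor`` times
    the maximum are dropped; if more than half the cells of a lag are
    dropped the result is flagged low-confidence.
    """
    jumps = {n: jump_pairs(traj, n, period_s) for n in lags}
    for n, j in jumps.items():
        if j.n_pairs < 500:
            raise ValueError(f"lag {n}T has only {j.n_pairs} pairs (need >= 500)")
    if dtheta_grid_deg is None:
        # span the support of the smallest lag: beyond ~2 sigma of the
        # narrowest jump distribution the KDE tails dominate the log-ratio
        dmax = min(
            abs(float(np.mean(j.dtheta_deg))) + 2.0 * float(np.std(j.dtheta_deg))
            for j in jumps.values()
        )
        dmax = max(dmax, 1.0)
        dtheta_grid_deg = np.linspace(-dmax, dmax, 25)
    dtheta_grid_deg = np.asarray(dtheta_grid_deg, dtype=float)
    theta0_grid = np.arange(theta0_grid_points) * (360.0 / theta0_grid_points)

    tt, dd = np.meshgrid(theta0_grid, dtheta_grid_deg, indexing="ij")
    ds = np.full((len(lags), dtheta_grid_deg.size), np.nan)
    low_conf = False
    for i, n in enumerate(lags):
        kde = transition_density(jumps[n], bandwidths_deg, max_pairs, bandwidth_scale)
        fwd = kde(tt.ravel(), dd.ravel()).reshape(tt.shape)
        bwd = kde(
            np.mod(tt + dd, 360.0).ravel(), (-dd).ravel()
        ).reshape(tt.shape)
        floor = density_floor * max(fwd.max(), bwd.max())
        valid = (fwd > floor) & (bwd > floor)
        if valid.mean() < 0.5:
            low_conf = True
        logratio = np.where(
            valid, np.log(np.maximum(fwd, floor)) - np.log(np.maximum(bwd, floor)), 0.0
        )
        n_valid = valid.sum(axis=0)
        with np.errstate(invalid="ignore"):
            curve = np.where(n_valid > 0, logratio.sum(axis=0) / np.maximum(n_valid, 1), np.nan)
        # antisymmetrize: the estimator must be odd in dtheta
        ds[i] = 0.5 * (curve - curve[::-1])

    slopes = np.array([_through_origin_slope(dtheta_grid_deg, ds[i]) for i in range(len(lags))])
    pooled = _through_origin_slope(
        np.tile(dtheta_grid_deg, len(lags)), ds.ravel()
    )
    omega, d_eff = effective_coefficients(traj, period_s, lags)
    ci = drift_bootstrap_ci(traj, period_s, seed=bootstrap_seed)
    return EntropyProductionCurve(
        lags=tuple(lags),
        dtheta_grid_deg=dtheta_grid_deg,
        ds_kb=ds,
        slopes_per_deg=slopes,
        slope=pooled,
        omega_eff_deg_s=omega,
        d_eff_deg2_s=d_eff,
        drift_ci_deg_s=ci,
        n_pairs=tuple(jumps[n].n_pairs for n in lags),
        low_confidence=low_conf,
        label=label,
    )


@dataclass
class CollapsedEnsemble:
    """Per-motor curves renormalized to unit slope, with exclusions."""

    curves: list[EntropyProductionCurve]
    collapsed_ds_kb: list[np.ndarray]
    included: list[int]
    excluded: list[int]
    pooled_slope: float


def renormalize_slopes(
    curves: list[EntropyProductionCurve],
    bias_threshold: float | None = None,
) -> CollapsedEnsemble:
    """Divide each motor's curve by its own slope and pool the ensemble.

    Motors without a significant bias are excluded (renormalization is
    ill-defined for them): by default those whose stroboscopic-drift 95%
    bootstrap CI contains zero; alternatively pass a numeric
    ``bias_threshold`` on |slope| (1/deg).
    """
    if len(curves) < 1:
        raise ValueError("need at least one curve")
    included, excluded = [], []
    for i, c in enumerate(curves):
        if bias_threshold is not None:
            ok = abs(c.slope) >= bias_threshold and math.isfinite(c.slope)
        else:
            ok = c.biased and math.isfinite(c.slope) and c.slope != 0.0
        (included if ok else excluded).append(i)
    if not included:
        raise ValueError("all motors excluded as unbiased; nothing to collapse")
    collapsed = []
    xs, ys = [], []
    for i in included:
        c = curves[i]
        scaled = c.ds_kb / c.slope
        collapsed.append(scaled)
        xs.append(np.tile(c.dtheta_grid_deg, len(c.lags)))
        ys.append(scaled.ravel())
    pooled = _through_origin_slope(np.concatenate(xs), np.concatenate(ys))
    return CollapsedEnsemble(
        curves=[curves[i] for i in included],
        collapsed_ds_kb=collapsed,
        included=included,
        excluded=excluded,
        pooled_slope=pooled,
    )


# --------------------------------------------------------------------------
# mean squared displacement


@dataclass
class MsdFit:
    """MSD(tau) = 2 D tau + (omega tau)^2 fit and the crossover time."""

    lags_s: np.ndarray
    msd_deg2: np.ndarray
    diffusion_deg2_s: float
    omega_deg_s: float
    crossover_time_s: float     # 2 D / omega^2; NaN when no ballistic term
    has_crossover: bool
    loglog_slope: np.ndarray


def msd_crossover(
    traj: AngularTrajectory,
    period_s: float | None = None,
    n_lags: int = 24,
    max_span_fraction: float = 0.25,
) -> MsdFit:
    """MSD over log-spaced lags and its drift-diffusion fit.

    For driven motors pass ``period_s`` to restrict lags to stroboscopic
    multiples of the field period. The fit is non-negative least squares
    of MSD against [2 tau, tau^2], giving D and omega^2; the crossover
    from diffusive to ballistic scaling is at t_c = 2 D / omega^2. When
    the ballistic term is pinned at zero the crossover is flagged absent.
    """
    theta = np.degrees(traj.theta)
    n = theta.size
    max_lag = int(n * max_span_fraction)
    if period_s is not None:
        strob = int(round(period_s / traj.dt))
        if abs(period_s / traj.dt - strob) > 1e-6:
            raise ValueError("period is not a multiple of the sampling interval")
        multiples = np.unique(
            np.round(np.geomspace(1, max(1, max_lag // strob), n_lags)).astype(int)
        )
        lag_frames = multiples * strob
    else:
        lag_frames = np.unique(np.round(np.geomspace(1, max_lag, n_lags)).astype(int))
    lag_frames = lag_frames[lag_frames < n]
    if lag_frames.size < 3:
        raise ValueError("trajectory too short for an MSD fit")
    taus = lag_frames * traj.dt
    msd = np.array([float(np.mean((theta[k:] - theta[:-k]) ** 2)) for k in lag_frames])
    design = np.column_stack([2.0 * taus, taus**2])
    # relative-error weights: sd(MSD) ~ MSD * sqrt(tau/span), so this
    # equalizes the information content of short and long lags
    w = 1.0 / (msd * np.sqrt(taus))
    coef, _ = scipy.optimize.nnls(design * w[:, None], msd * w)
    d_eff, omega_sq = float(coef[0]), float(coef[1])
    mean_drift = float(np.mean(np.diff(theta))) / traj.dt
    omega = math.copysign(math.sqrt(omega_sq), mean_drift) if omega_sq > 0 else 0.0
    # ballistic term is "present" when it dominates within the fitted range
    has = omega_sq > 0 and d_eff >= 0 and (omega_sq * taus[-1] ** 2) > 0.05 * (
        2 * d_eff * taus[-1]
    )
    t_c = 2.0 * d_eff / omega_sq if (has and omega_sq > 0) else math.nan
    with np.errstate(divide="ignore"):
        log_t, log_m = np.log(taus), np.log(msd)
    slope = np.gradient(log_m, log_t)
    return MsdFit(
        lags_s=taus,
        msd_deg2=msd,
        diffusion_deg2_s=d_eff,
        omega_deg_s=omega,
        crossover_time_s=t_c,
        has_crossover=bool(has),
        loglog_slope=slope,
    )
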