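"""Trajectory statistics for tracked rotor tips.

Implements the single-particle observables used to characterize the
motors: angle extraction from tip positions, unwrapping into cumulative
angular displacement, the endpoint angular-velocity formula
``Omega = (theta_last - theta_first) / dt``, speed histograms with CW/CCW
fractions, phase-corrected speed versus field-axis fits, turns per field
cycle, and dwell-position detection from the wrapped-angle histogram.

Convention: angles CCW-positive, x right, y up; degrees at the interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.signal
import scipy.stats

from .simulate import AngularTrajectory
from .synthetic_tirf import TipPositionSeries

__all__ = [
    "SpeedRecord",
    "AxisFit",
    "angles_from_positions",
    "unwrap",
    "angular_velocity",
    "speed_histogram",
    "speed_vs_axis",
    "speed_vs_axis_ensemble",
    "segment_speeds",
    "turns_per_cycle",
    "dwell_positions",
    "robust_slope",
]

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class SpeedRecord:
    """Angular speed of one particle in one protocol segment."""

    particle_id: str
    segment: str
    omega_deg_s: float
    frequency_hz: float | None = None

    @property
    def turns_per_cycle(self) -> float:
        if not self.frequency_hz:
            return math.nan
        return self.omega_deg_s / (360.0 * self.frequency_hz)


def angles_from_positions(series: TipPositionSeries) -> np.ndarray:
    """Wrapped tip angle atan2(y - cy, x - cx) per frame, in (-pi, pi]."""
    dx = series.x_nm - series.center_x_nm
    dy = series.y_nm - series.center_y_nm
    r2 = dx * dx + dy * dy
    zero = np.nonzero(r2 == 0.0)[0]
    if zero.size:
        raise ValueError(f"tip coincides with the rotation center at frame {int(zero[0])}")
    ang = np.arctan2(dy, dx)
    # atan2 returns [-pi, pi]; fold -pi onto +pi for the (-pi, pi] convention
    ang[ang == -math.pi] = math.pi
    return ang


def unwrap(wrapped: np.ndarray) -> np.ndarray:
    """Cumulative angle: successive differences mapped to (-pi, pi].

    Ties (a jump of exactly pi) are resolved toward +pi. The first value
    equals the first wrapped angle.
    """
    wrapped = np.asarray(wrapped, dtype=float)
    if wrapped.size == 0:
        return wrapped.copy()
    d = np.diff(wrapped)
    # map to (-pi, pi]: pi - ((pi - d) mod 2*pi)
    d = math.pi - np.mod(math.pi - d, TWO_PI)
    return np.concatenate([[wrapped[0]], wrapped[0] + np.cumsum(d)])


def _window_indices(times: np.ndarray, window) -> tuple[int, int]:
    t0, t1 = float(window[0]), float(window[1])
    if t1 <= t0:
        raise ValueError("window must satisfy t_last > t_first")
    eps = 1e-9 * max(1.0, abs(t1))
    i0 = int(np.searchsorted(times, t0 - eps, side="left"))
    i1 = int(np.searchsorted(times, t1 + eps, side="right")) - 1
    if i0 >= times.size or i1 < 0 or i1 <= i0:
        raise ValueError(f"window [{t0}, {t1}] contains fewer than two samples")
    return i0, i1


def angular_velocity(traj: AngularTrajectory, window=None) -> float:
    """Endpoint angular velocity Omega = (theta_last - theta_first)/dt, deg/s.

    Exactly the first/last-frame formula (not a regression slope); sign is
    CCW-positive.
    """
    if window is None:
        window = (traj.times[0], traj.times[-1])
    i0, i1 = _window_indices(traj.times, window)
    omega_rad = (traj.theta[i1] - traj.theta[i0]) / (traj.times[i1] - traj.times[i0])
    return math.degrees(omega_rad)


def robust_slope(traj: AngularTrajectory, window=None) -> float:
    """Diagnostic Theil-Sen slope (deg/s); never used by the endpoint paths."""
    if window is None:
        window = (traj.times[0], traj.times[-1])
    i0, i1 = _window_indices(traj.times, window)
    t = traj.times[i0 : i1 + 1]
    y = traj.theta[i0 : i1 + 1]
    if t.size > 2000:  # Theil-Sen is O(n^2); subsample the window
        sel = np.linspace(0, t.size - 1, 2000).astype(int)
        t, y = t[sel], y[sel]
    res = scipy.stats.theilslopes(y, t)
    return math.degrees(res.slope)


def speed_histogram(records, bin_width: float = 30.0) -> dict:
    """Histogram of signed angular speeds (deg/s) with CW/CCW fractions.

    ``records`` is a sequence of SpeedRecord or of plain signed speeds.
    """
    speeds = np.asarray(
        [r.omega_deg_s if isinstance(r, SpeedRecord) else float(r) for r in records]
    )
    if speeds.size == 0:
        raise ValueError("speed_histogram needs at least one record")
    lo = math.floor(speeds.min() / bin_width) * bin_width
    hi = math.ceil(speeds.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    counts, edges = np.histogram(speeds, bins=edges)
    return {
        "counts": counts,
        "bin_edges": edges,
        "n": speeds.size,
        "mean": float(speeds.mean()),
        "ccw_fraction": float((speeds > 0).mean()),
        "cw_fraction": float((speeds < 0).mean()),
    }


def segment_speeds(
    traj: AngularTrajectory,
    boundaries: Sequence[float] | None = None,
    particle_id: str = "0",
    labels: Sequence[dict] | None = None,
) -> list[SpeedRecord]:
    """Endpoint speed per protocol segment.

    Boundaries default to the segment boundaries stored in the trajectory
    metadata by the simulator.
    """
    if boundaries is None:
        boundaries = traj.metadata.get("segment_boundaries_s")
        if boundaries is None:
            raise ValueError("no segment boundaries given or found in metadata")
    if labels is None:
        labels = traj.metadata.get("segment_labels")
    out = []
    for k in range(len(boundaries) - 1):
        lab = labels[k] if labels else {}
        name = lab.get("waveform", f"segment{k}")
        freq = None
        if lab.get("period_s"):
            freq = 1.0 / lab["period_s"]
        if lab.get("waveform") in ("dc", "off"):
            freq = None
        omega = angular_velocity(traj, (boundaries[k], boundaries[k + 1]))
        out.append(
            SpeedRecord(
                particle_id=particle_id,
                segment=f"{name}:{k}",
                omega_deg_s=omega,
                frequency_hz=freq,
            )
        )
    return out


@dataclass
class AxisFit:
    """Sinusoidal fit Omega(phi) = A sin(k (phi - phi0)) + m (degrees)."""

    amplitude: float
    phase_deg: float
    offset: float
    harmonic: int
    axes_deg: np.ndarray
    speeds_deg_s: np.ndarray
    residuals: np.ndarray
    r_squared: float
    p_value: float

    def phase_corrected_axes(self) -> np.ndarray:
        """Axes shifted so the fitted phase is zero (per-particle alignment)."""
        return self.axes_deg - self.phase_deg

    def predict(self, axes_deg) -> np.ndarray:
        phi = np.radians(np.asarray(axes_deg, dtype=float))
        return self.amplitude * np.sin(
            self.harmonic * (phi - math.radians(self.phase_deg))
        ) + self.offset


def speed_vs_axis(
    traj: AngularTrajectory,
    axis_schedule: Sequence[tuple[float, float, float]] | None = None,
    harmonic: int = 2,
) -> AxisFit:
    """Per-axis-segment speeds and their sinusoidal fit.

    The response of the motor to the field-axis angle phi has period
    180 deg by default (harmonic=2): the square-wave field has no net
    polarity, so phi and phi+180 are equivalent. The fit is linear least
    squares via Omega = alpha sin(k phi) + beta cos(k phi) + m, and the
    p-value is an F-test of the sinusoid against a constant.
    """
    if axis_schedule is None:
        bounds = traj.metadata.get("segment_boundaries_s")
        labels = traj.metadata.get("segment_labels")
        if bounds is None or labels is None:
            raise ValueError("no axis schedule given or found in metadata")
        axis_schedule = [
            (bounds[k], bounds[k + 1], labels[k]["axis_deg"]) for k in range(len(labels))
        ]
    if len(axis_schedule) < 4:
        raise ValueError("axis sweep fit needs at least 4 segments")
    axes = np.array([s[2] for s in axis_schedule], dtype=float)
    speeds = np.array(
        [angular_velocity(traj, (s[0], s[1])) for s in axis_schedule], dtype=float
    )
    return _axis_fit_from_points(axes, speeds, harmonic)


def _axis_fit_from_points(axes: np.ndarray, speeds: np.ndarray, harmonic: int) -> AxisFit:
    phi = np.radians(axes)
    design = np.column_stack(
        [np.sin(harmonic * phi), np.cos(harmonic * phi), np.ones_like(phi)]
    )
    coef, *_ = np.linalg.lstsq(design, speeds, rcond=None)
    alpha, beta, m = coef
    amp = math.hypot(alpha, beta)
    phi0 = -math.atan2(beta, alpha) / harmonic
    fitted = design @ coef
    resid = speeds - fitted
    ss_res = float(resid @ resid)
    ss_tot = float(((speeds - speeds.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    n, p_full, p_null = speeds.size, 3, 1
    if ss_res <= 0:
        p_value = 0.0
    else:
        f_stat = ((ss_tot - ss_res) / (p_full - p_null)) / (ss_res / (n - p_full))
        p_value = float(scipy.stats.f.sf(f_stat, p_full - p_null, n - p_full))
    return AxisFit(
        amplitude=amp,
        phase_deg=math.degrees(phi0),
        offset=float(m),
        harmonic=harmonic,
        axes_deg=axes,
        speeds_deg_s=speeds,
        residuals=resid,
        r_squared=r2,
        p_value=p_value,
    )


def speed_vs_axis_ensemble(trajs: Sequence[AngularTrajectory], harmonic: int = 2) -> AxisFit:
    """Axis-response fit on the ensemble-averaged speed-vs-axis curve.

    Per-segment endpoint speeds over a single 1.6 s dwell are dominated by
    diffusive noise; averaging the per-axis speeds over replicate runs of
    the same motor (same axis schedule, independent noise) recovers the
    clean sinusoidal response before fitting, mirroring ensemble-averaged
    single-particle experiments.
    """
    if not trajs:
        raise ValueError("need at least one trajectory")
    all_speeds = []
    ref_axes = None
    for traj in trajs:
        bounds = traj.metadata.get("segment_boundaries_s")
        labels = traj.metadata.get("segment_labels")
        if bounds is None or labels is None:
            raise ValueError("trajectory metadata lacks an axis schedule")
        axes = np.array([lab["axis_deg"] for lab in labels], dtype=float)
        if ref_axes is None:
            ref_axes = axes
        elif not np.array_equal(axes, ref_axes):
            raise ValueError("all trajectories must share the same axis schedule")
        all_speeds.append(
            [angular_velocity(traj, (bounds[k], bounds[k + 1])) for k in range(len(labels))]
        )
    mean_speeds = np.asarray(all_speeds, dtype=float).mean(axis=0)
    if ref_axes.size < 4:
        raise ValueError("axis sweep fit needs at least 4 segments")
    return _axis_fit_from_points(ref_axes, mean_speeds, harmonic)


def turns_per_cycle(omega_deg_s: float, frequency_hz: float) -> float:
    """Directional bias efficiency: net turns per AC field cycle.

    Undefined at zero frequency (DC/off); returns NaN as the flagged
    missing value.
    """
    if frequency_hz < 0:
        raise ValueError("frequency must be >= 0")
    if frequency_hz == 0:
        return math.nan
    return omega_deg_s / (360.0 * frequency_hz)


def dwell_positions(
    wrapped_angles: np.ndarray,
    bin_deg: float = 5.0,
    prominence: float = 0.2,
    min_frames: int = 10_000,
) -> np.ndarray:
    """Preferred dwell angles from the wrapped-angle histogram (degrees).

    Peaks are detected circularly (the histogram is tiled before
    scipy.signal.find_peaks) with relative prominence >= ``prominence`` of
    the maximum bin count. Returns peak centers in [0, 360).
    """
    ang = np.mod(np.degrees(np.asarray(wrapped_angles, dtype=float)), 360.0)
    if ang.size < min_frames:
        raise ValueError(f"dwell detection needs >= {min_frames} frames, got {ang.size}")
    nbins = int(round(360.0 / bin_deg))
    counts, edges = np.histogram(ang, bins=nbins, range=(0.0, 360.0))
    if counts.max() == counts.min():
        return np.array([])
    tiled = np.concatenate([counts, counts, counts]).astype(float)
    peaks, _ = scipy.signal.find_peaks(tiled, prominence=prominence * counts.max())
    centers = (edges[:-1] + edges[1:]) / 2.0
    sel = peaks[(peaks >= nbins) & (peaks < 2 * nbins)] - nbins
    return np.sort(centers[sel])
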