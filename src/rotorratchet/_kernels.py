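"""Numba inner loops for the Euler-Maruyama integrator.

The kernel is deliberately flat: per-step it evaluates the analytic
gradient of the landscape (Gaussian image wells + field term + optional
torsional spring) and advances the overdamped Langevin update. All
waveform/segment logic is reduced to plain float/int arrays before entry.
"""

from __future__ import annotations

import math

import numba
import numpy as np

# waveform codes must match landscape._WAVEFORM_CODES
_OFF, _SQUARE, _SMOOTHED, _DC = 0, 1, 2, 3


@numba.njit(cache=True, fastmath=False)
def _field_e(code: int, t: float, period: float, order: int, printed: bool) -> float:
    if code == _OFF:
        return 0.0
    if code == _DC:
        return 1.0
    if code == _SQUARE:
        return 1.0 if (t % period) < 0.5 * period else -1.0
    # smoothed square
    acc = 0.0
    if printed:
        for n in range(1, order + 1):
            acc += math.sin(n * t / period) / n
    else:
        for n in range(1, order + 1, 2):
            acc += math.sin(2.0 * math.pi * n * t / period) / n
        acc *= 4.0 / math.pi
    return acc


@numba.njit(cache=True, fastmath=False)
def _intrinsic_grad(theta: float, b: float, c: float, theta0: float,
                    spacing: float, n_images: int) -> float:
    d = ((theta - theta0 + math.pi) % (2.0 * math.pi)) - math.pi
    k0 = round(d / spacing)
    acc = 0.0
    for m in range(-n_images, n_images + 1):
        x = d - (k0 + m) * spacing
        acc += 2.0 * c * x * math.exp(-c * x * x)
    return b * acc


@numba.njit(cache=True, fastmath=False)
def integrate(
    theta_init: float,
    dt: float,
    damping: float,
    noise_amp: float,          # sqrt(2 * kT * dt / damping); 0 for deterministic
    seg_steps: np.ndarray,     # int64[n_seg]
    seg_code: np.ndarray,      # int64[n_seg]
    seg_period: np.ndarray,    # float64[n_seg]
    seg_pref: np.ndarray,      # float64[n_seg], (4a/pi) * amplitude_scale
    seg_axis: np.ndarray,      # float64[n_seg]
    seg_order: np.ndarray,     # int64[n_seg]
    seg_printed: np.ndarray,   # bool_[n_seg]
    b: float,
    c: float,
    theta0: float,
    spacing: float,
    n_images: int,
    kappa: float,
    anchor: float,
    noise: np.ndarray,         # float64[total_steps] standard normals
    record_stride: int,
):
    """Advance the trajectory; returns (recorded_theta, fail_step).

    fail_step is -1 on success, else the index of the first non-finite step.
    """
    total_steps = 0
    for i in range(seg_steps.size):
        total_steps += seg_steps[i]
    n_rec = total_steps // record_stride + 1
    out = np.empty(n_rec, dtype=np.float64)
    theta = theta_init
    out[0] = theta
    step = 0
    for s in range(seg_steps.size):
        code = seg_code[s]
        period = seg_period[s]
        pref = seg_pref[s]
        axis = seg_axis[s]
        order = seg_order[s]
        printed = seg_printed[s]
        t_local = 0.0
        for _ in range(seg_steps[s]):
            e = _field_e(code, t_local, period, order, printed)
            grad = -pref * e * math.sin(theta - axis)
            grad += _intrinsic_grad(theta, b, c, theta0, spacing, n_images)
            if kappa > 0.0:
                grad += kappa * (theta - anchor)
            theta = theta - (grad / damping) * dt + noise_amp * noise[step]
            if not math.isfinite(theta):
                return out, step
            t_local += dt
            step += 1
            if step % record_stride == 0:
                out[step // record_stride] = theta
    return out, -1
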