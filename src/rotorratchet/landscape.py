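"""Time-dependent 1D energy landscape of the rotary ratchet.

The rotor arm lives on a circle and feels two contributions:

* an intrinsic, time-independent potential made of ``n_minima`` Gaussian
  wells of depth ``b`` (kBT) and inverse squared width ``c`` (rad^-2),
  spaced ``2*pi/n_minima`` apart and offset by ``theta0``;
* a field term ``(4a/pi) * cos(theta - phi_axis) * E(t)`` where ``E(t)``
  is a square-wave (or smoothed) AC drive of period ``T``.

Energies are in thermal units (kBT); angles are radians internally and
degrees at every I/O boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "RotorLandscape",
    "FieldSegment",
    "FieldProtocol",
    "square_wave",
    "smoothed_square_wave",
    "intrinsic_potential",
    "intrinsic_grad",
    "total_potential",
    "grad_potential",
    "field_amplitude_prefactor",
]

TWO_PI = 2.0 * math.pi

Waveform = Literal["square", "smoothed_square", "dc", "off"]

_WAVEFORM_CODES = {"off": 0, "square": 1, "smoothed_square": 2, "dc": 3}


@dataclass(frozen=True)
class RotorLandscape:
    """Intrinsic periodic well structure plus field coupling strength.

    Parameters
    ----------
    field_strength:
        Field coupling ``a`` (kBT). The field term in the potential is
        ``(4a/pi) * cos(theta - phi_axis) * E(t)``.
    well_depth:
        Depth ``b`` of each Gaussian well (kBT), ``b >= 0``.
    well_inverse_width:
        Inverse squared width ``c`` (rad^-2), ``c > 0``.
    minima_offset:
        Angle ``theta0`` of one well center (rad).
    n_minima:
        Number of wells per turn; spacing is forced to ``2*pi/n_minima``.
    """

    field_strength: float = 4.0
    well_depth: float = 4.0
    well_inverse_width: float = 10.0
    minima_offset: float = 0.0
    n_minima: int = 2

    def __post_init__(self) -> None:
        if self.n_minima < 1 or int(self.n_minima) != self.n_minima:
            raise ValueError("n_minima must be a positive integer")
        if self.well_depth < 0:
            raise ValueError("well_depth must be >= 0")
        if self.well_inverse_width <= 0:
            raise ValueError("well_inverse_width must be > 0")
        if self.field_strength < 0:
            raise ValueError("field_strength must be >= 0")

    @property
    def minima_spacing(self) -> float:
        """Well spacing (rad); always an exact fraction of 2*pi."""
        return TWO_PI / self.n_minima

    @property
    def n_images(self) -> int:
        # Gaussian tails: images beyond 6 standard widths contribute < 1e-12.
        return math.ceil(6.0 / (math.sqrt(self.well_inverse_width) * self.minima_spacing)) + 1

    def mirrored(self) -> "RotorLandscape":
        """Landscape reflected through theta = 0 (theta0 -> -theta0)."""
        return replace(self, minima_offset=-self.minima_offset)


@dataclass(frozen=True)
class FieldSegment:
    """One piece of a field protocol: a waveform held for a fixed duration."""

    duration: float
    waveform: Waveform = "square"
    period: float | None = None
    amplitude_scale: float = 1.0
    axis_angle: float = 0.0
    fourier_order: int | None = None
    dialect: str = "standard"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("segment duration must be > 0")
        if self.waveform not in _WAVEFORM_CODES:
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if self.waveform in ("square", "smoothed_square"):
            if self.period is None or self.period <= 0:
                raise ValueError("square/smoothed segments need period > 0")
        if self.waveform == "smoothed_square":
            if self.fourier_order is None or self.fourier_order < 1:
                raise ValueError("smoothed_square needs fourier_order >= 1")
        if self.amplitude_scale < 0:
            raise ValueError("amplitude_scale must be >= 0")

    @property
    def waveform_code(self) -> int:
        return _WAVEFORM_CODES[self.waveform]


@dataclass(frozen=True)
class FieldProtocol:
    """Ordered sequence of field segments."""

    segments: tuple[FieldSegment, ...]

    def __init__(self, segments: Sequence[FieldSegment]):
        object.__setattr__(self, "segments", tuple(segments))
        if not self.segments:
            raise ValueError("protocol needs at least one segment")

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    def segment_boundaries(self) -> np.ndarray:
        """Start/end times of the segments; length n_segments + 1."""
        return np.concatenate([[0.0], np.cumsum([s.duration for s in self.segments])])

    def locate(self, t: float) -> tuple[FieldSegment, float]:
        """Segment containing time ``t`` and the segment-local time."""
        if t < 0 or t > self.total_duration * (1 + 1e-12):
            raise ValueError(f"t={t} outside protocol duration {self.total_duration}")
        start = 0.0
        for seg in self.segments:
            if t < start + seg.duration or seg is self.segments[-1]:
                return seg, t - start
            start += seg.duration
        raise AssertionError("unreachable")

    @staticmethod
    def constant(
        duration: float,
        waveform: Waveform = "square",
        period: float = 0.2,
        amplitude_scale: float = 1.0,
        axis_angle: float = 0.0,
        fourier_order: int | None = None,
    ) -> "FieldProtocol":
        """Single-segment protocol (convenience constructor)."""
        kw = {}
        if waveform in ("square", "smoothed_square"):
            kw["period"] = period
        if waveform == "smoothed_square":
            kw["fourier_order"] = fourier_order or 99
        return FieldProtocol(
            [
                FieldSegment(
                    duration=duration,
                    waveform=waveform,
                    amplitude_scale=amplitude_scale,
                    axis_angle=axis_angle,
                    **kw,
                )
            ]
        )


def square_wave(t, period: float):
    """Square-wave drive: +1 on the first half-period, -1 on the second.

    Periodic with ``period``; the time average over any whole number of
    periods is exactly zero.
    """
    if period <= 0:
        raise ValueError("period must be > 0")
    t = np.asarray(t, dtype=float)
    out = np.where(np.mod(t, period) < 0.5 * period, 1.0, -1.0)
    return out if out.ndim else float(out)


def smoothed_square_wave(t, period: float, order: int, dialect: str = "standard"):
    """Fourier partial-sum approximation of the square-wave drive.

    dialect="standard" is the conventional square-wave Fourier series
    ``(4/pi) * sum_{odd n <= order} sin(2*pi*n*t/T)/n``, which converges
    to :func:`square_wave` away from the discontinuities.

    dialect="printed" is ``sum_{n=1..order} sin(n*t/T)/n`` — a sawtooth-like
    sum kept for comparison with an alternative published convention.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    if period <= 0:
        raise ValueError("period must be > 0")
    t = np.asarray(t, dtype=float)
    if dialect == "printed":
        ns = np.arange(1, order + 1)
        out = np.sin(np.multiply.outer(t, ns) / period) @ (1.0 / ns)
    elif dialect == "standard":
        ns = np.arange(1, order + 1, 2)
        out = (4.0 / math.pi) * (
            np.sin(np.multiply.outer(t, ns) * (TWO_PI / period)) @ (1.0 / ns)
        )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    return out if out.ndim else float(out)


def _waveform_value(seg: FieldSegment, t_local) -> float | np.ndarray:
    if seg.waveform == "off":
        return np.zeros_like(np.asarray(t_local, dtype=float)) if np.ndim(t_local) else 0.0
    if seg.waveform == "dc":
        return np.ones_like(np.asarray(t_local, dtype=float)) if np.ndim(t_local) else 1.0
    if seg.waveform == "square":
        return square_wave(t_local, seg.period)
    return smoothed_square_wave(t_local, seg.period, seg.fourier_order, seg.dialect)


def field_amplitude_prefactor(landscape: RotorLandscape) -> float:
    """Prefactor 4a/pi of the field term (kBT)."""
    return 4.0 * landscape.field_strength / math.pi


def intrinsic_potential(theta, landscape: RotorLandscape):
    """Static well potential -b * sum_n exp(-c (theta - theta0 - n*dtheta)^2).

    The image sum is truncated where Gaussian tails fall below 1e-12, and
    the result is exactly 2*pi-periodic by construction (the displacement
    is wrapped before summing images).
    """
    theta = np.asarray(theta, dtype=float)
    d = np.mod(theta - landscape.minima_offset + math.pi, TWO_PI) - math.pi
    # nearest well index within one period, then sum surrounding images
    spacing = landscape.minima_spacing
    k0 = np.round(d / spacing)
    acc = np.zeros_like(d)
    c = landscape.well_inverse_width
    for m in range(-landscape.n_images, landscape.n_images + 1):
        x = d - (k0 + m) * spacing
        acc += np.exp(-c * x * x)
    out = -landscape.well_depth * acc
    return out if out.ndim else float(out)


def intrinsic_grad(theta, landscape: RotorLandscape):
    """d/dtheta of :func:`intrinsic_potential`."""
    theta = np.asarray(theta, dtype=float)
    d = np.mod(theta - landscape.minima_offset + math.pi, TWO_PI) - math.pi
    spacing = landscape.minima_spacing
    k0 = np.round(d / spacing)
    acc = np.zeros_like(d)
    c = landscape.well_inverse_width
    for m in range(-landscape.n_images, landscape.n_images + 1):
        x = d - (k0 + m) * spacing
        acc += 2.0 * c * x * np.exp(-c * x * x)
    out = landscape.well_depth * acc
    return out if out.ndim else float(out)


def total_potential(theta, t, landscape: RotorLandscape, protocol: FieldProtocol):
    """U(theta, t): field term plus intrinsic wells (kBT).

    The field term is ``(4a/pi) * cos(theta - phi_axis) * E(t_local) *
    amplitude_scale`` of the protocol segment containing ``t``; it vanishes
    for ``waveform="off"``.
    """
    seg, t_local = protocol.locate(float(t))
    e = _waveform_value(seg, t_local)
    pref = field_amplitude_prefactor(landscape) * seg.amplitude_scale * e
    theta = np.asarray(theta, dtype=float)
    out = pref * np.cos(theta - seg.axis_angle) + intrinsic_potential(theta, landscape)
    return out if out.ndim else float(out)


def grad_potential(theta, t, landscape: RotorLandscape, protocol: FieldProtocol):
    """dU/dtheta (kBT/rad) — the negative of the generalized torque."""
    seg, t_local = protocol.locate(float(t))
    e = _waveform_value(seg, t_local)
    pref = field_amplitude_prefactor(landscape) * seg.amplitude_scale * e
    theta = np.asarray(theta, dtype=float)
    out = -pref * np.sin(theta - seg.axis_angle) + intrinsic_grad(theta, landscape)
    return out if out.ndim else float(out)
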