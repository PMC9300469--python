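"""Shared fixtures and deterministic hypothesis settings."""

import math

import pytest
from hypothesis import HealthCheck, settings

from rotorratchet import (
    FieldProtocol,
    RotorLandscape,
    SimulationConfig,
    simulate,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def biased_landscape() -> RotorLandscape:
    """Two-well motor with wells offset 45 deg from the field axis."""
    return RotorLandscape(minima_offset=math.radians(45.0))


@pytest.fixture(scope="session")
def symmetric_landscape() -> RotorLandscape:
    """Two-well motor with wells on the field axis (no broken symmetry)."""
    return RotorLandscape(minima_offset=0.0)


@pytest.fixture(scope="session")
def short_drive() -> FieldProtocol:
    """4 s (20 cycles) of the 5 Hz square drive."""
    return FieldProtocol.constant(4.0, waveform="square", period=0.2)


@pytest.fixture(scope="session")
def driven_trajectory(biased_landscape, short_drive):
    """A short driven trajectory reused by read-only tests."""
    return simulate(biased_landscape, short_drive, SimulationConfig(seed=11))
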