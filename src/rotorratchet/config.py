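"""Run configuration: validated, serializable, reproducible.

A RunConfig bundles landscape, protocol, integrator, rendering and
analysis settings plus one global seed. Per-stage seeds are derived
deterministically from the global seed with numpy's SeedSequence
(spawn key = stage index), so stages can be re-run in isolation.
Configs round-trip through YAML or JSON; unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
import math
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .landscape import FieldProtocol, FieldSegment, RotorLandscape
from .simulate import SimulationConfig

__all__ = [
    "LandscapeConfig",
    "SegmentConfig",
    "IntegratorConfig",
    "RenderConfig",
    "AnalysisConfig",
    "SpringSpec",
    "RunConfig",
    "validate_config",
    "ConfigError",
]

_STAGES = ("simulate", "render", "analyze", "thermo")


class ConfigError(ValueError):
    """Raised with an aggregated, human-readable list of config problems."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class LandscapeConfig(_Strict):
    a_kT: float = Field(4.0, ge=0)
    b_kT: float = Field(4.0, ge=0)
    c_per_rad2: float = Field(10.0, gt=0)
    theta0_deg: float = 45.0
    n_minima: int = Field(2, ge=1)

    def build(self) -> RotorLandscape:
        return RotorLandscape(
            field_strength=self.a_kT,
            well_depth=self.b_kT,
            well_inverse_width=self.c_per_rad2,
            minima_offset=math.radians(self.theta0_deg),
            n_minima=self.n_minima,
        )


class SegmentConfig(_Strict):
    duration_s: float = Field(gt=0)
    waveform: Literal["square", "smoothed_square", "dc", "off"] = "square"
    period_s: float | None = Field(None, gt=0)
    amplitude_scale: float = Field(1.0, ge=0)
    axis_deg: float = 0.0
    fourier_order: int | None = Field(None, ge=1)
    dialect: Literal["standard", "printed"] = "standard"

    @model_validator(mode="after")
    def _needs_period(self):
        if self.waveform in ("square", "smoothed_square") and self.period_s is None:
            raise ValueError(f"waveform {self.waveform!r} requires period_s")
        if self.waveform == "smoothed_square" and self.fourier_order is None:
            raise ValueError("smoothed_square requires fourier_order")
        return self

    def build(self) -> FieldSegment:
        return FieldSegment(
            duration=self.duration_s,
            waveform=self.waveform,
            period=self.period_s,
            amplitude_scale=self.amplitude_scale,
            axis_angle=math.radians(self.axis_deg),
            fourier_order=self.fourier_order,
            dialect=self.dialect,
        )


class IntegratorConfig(_Strict):
    damping: float = Field(0.1, gt=0)
    thermal_energy: float = Field(1.0, ge=0)
    dt_s: float = Field(2e-5, gt=0)
    record_stride: int = Field(200, ge=1)
    initial_angle_deg: float | None = None

    def build(self, seed: int) -> SimulationConfig:
        return SimulationConfig(
            damping=self.damping,
            thermal_energy=self.thermal_energy,
            dt=self.dt_s,
            record_stride=self.record_stride,
            seed=seed,
            initial_angle=(
                math.radians(self.initial_angle_deg)
                if self.initial_angle_deg is not None
                else None
            ),
        )


class RenderConfig(_Strict):
    rotor_radius_nm: float = Field(275.0, gt=0)
    localization_sigma_nm: float = Field(20.0, ge=0)
    frame_rate_hz: float = Field(250.0, gt=0)


class AnalysisConfig(_Strict):
    period_s: float = Field(0.2, gt=0)
    lags: tuple[int, ...] = (2, 4, 6)
    transient_cycles: int = Field(10, ge=0)
    speed_bin_deg_s: float = Field(30.0, gt=0)
    dwell_bin_deg: float = Field(5.0, gt=0)
    dwell_prominence: float = Field(0.2, gt=0, le=1)


class SpringSpec(_Strict):
    stiffness_kT_rad2: float = Field(0.05, ge=0)
    anchor_deg: float = 45.0


class RunConfig(_Strict):
    landscape: LandscapeConfig = LandscapeConfig()
    segments: tuple[SegmentConfig, ...] = (
        SegmentConfig(duration_s=40.0, waveform="square", period_s=0.2),
    )
    integrator: IntegratorConfig = IntegratorConfig()
    render: RenderConfig = RenderConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    spring: SpringSpec | None = None
    seed: int = 1
    output_dir: str = "rotorratchet_run"

    def build_protocol(self) -> FieldProtocol:
        return FieldProtocol([s.build() for s in self.segments])

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed from the global seed."""
        idx = _STAGES.index(stage)
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(idx,))
        return int(ss.generate_state(1)[0] % (2**31))

    def to_dict(self) -> dict:
        return json.loads(self.model_dump_json())

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def validate_config(raw: str | dict) -> RunConfig:
    """Parse and validate a YAML/JSON config text (or a dict).

    All defaults are materialized; unknown keys are rejected. Problems are
    aggregated into a single ConfigError listing every offending field.
    """
    if isinstance(raw, str):
        try:
            data = yaml.safe_load(raw)
        except yaml.YAMLError as e:
            raise ConfigError(f"could not parse config: {e}") from e
    else:
        data = raw
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    try:
        cfg = RunConfig.model_validate(data)
    except ValidationError as e:
        lines = []
        for err in e.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<root>"
            lines.append(f"{loc}: {err['msg']}")
        raise ConfigError("invalid config:\n  " + "\n  ".join(lines)) from e
    # cross-check the integrator stability bound before any computation
    sim = cfg.integrator.build(seed=0)
    kappa = cfg.spring.stiffness_kT_rad2 if cfg.spring else 0.0
    try:
        sim.check_stability(cfg.landscape.build(), kappa)
    except ValueError as e:
        raise ConfigError(f"invalid config:\n  integrator.dt_s: {e}") from e
    return cfg
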