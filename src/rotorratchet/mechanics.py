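"""Analytic motor-mechanics calculators.

Rotational friction of a rod stirring the solvent (zeta_r = pi eta L^3),
torque tau = zeta_r * omega, dissipated power zeta_r * omega^2 with
conversions to kBT/s and ATP-hydrolysis equivalents, the linear load line
omega(tau) = omega_eff - tau/zeta_r, and the nominal efficiency
epsilon(tau) = (omega_eff - tau/zeta_r) tau / (zeta_eff omega_eff^2) with
its bound epsilon <= zeta_r / (4 zeta_eff).

SI inputs (Pa*s, m, N*m*s, rad/s); torques and powers are reported in
pN*nm (1 pN*nm = 1e-21 N*m).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

__all__ = [
    "BOLTZMANN_J_PER_K",
    "MechanicsReport",
    "rotational_friction",
    "torque_from_speed",
    "dissipated_power",
    "loaded_velocity",
    "efficiency",
    "mechanics_report",
]

BOLTZMANN_J_PER_K = 1.380649e-23
PN_NM_PER_J = 1e21  # 1 J = 1e21 pN*nm


def rotational_friction(viscosity_pa_s: float, length_m: float) -> float:
    """Rotational friction coefficient zeta_r = pi * eta * L^3 (N*m*s)."""
    if viscosity_pa_s <= 0:
        raise ValueError("viscosity must be > 0")
    if length_m <= 0:
        raise ValueError("rotor length must be > 0")
    return math.pi * viscosity_pa_s * length_m**3


def torque_from_speed(zeta_r: float, omega_rad_s: float) -> float:
    """Frictional torque tau = zeta_r * omega, in pN*nm."""
    if zeta_r <= 0:
        raise ValueError("zeta_r must be > 0")
    return zeta_r * omega_rad_s * PN_NM_PER_J


def dissipated_power(
    zeta_r: float,
    omega_rad_s: float,
    temperature_k: float = 293.0,
    atp_energy_kt: float = 25.0,
) -> dict:
    """Power dissipated against friction, in three unit systems.

    Returns power = zeta_r * omega^2 in pN*nm/s, in kBT/s at the given
    temperature, and as ATP molecules hydrolyzed per second at the given
    free energy per ATP (kBT units).
    """
    if temperature_k <= 0:
        raise ValueError("temperature must be > 0")
    if atp_energy_kt <= 0:
        raise ValueError("ATP free energy must be > 0")
    power_w = zeta_r * omega_rad_s**2
    kt_pn_nm = BOLTZMANN_J_PER_K * temperature_k * PN_NM_PER_J
    power_pn_nm = power_w * PN_NM_PER_J
    power_kt = power_pn_nm / kt_pn_nm
    return {
        "power_pn_nm_s": power_pn_nm,
        "power_kt_s": power_kt,
        "atp_per_s": power_kt / atp_energy_kt,
        "kt_pn_nm": kt_pn_nm,
    }


def loaded_velocity(omega_eff: float, tau: float, zeta_r: float) -> float:
    """Net angular velocity against an external torque: omega_eff - tau/zeta_r.

    ``tau`` in the same energy*time-free units as ``zeta_r * omega`` (SI:
    N*m against N*m*s and rad/s). May be negative (overdriven load).
    """
    if zeta_r <= 0:
        raise ValueError("zeta_r must be > 0")
    return omega_eff - tau / zeta_r


def efficiency(
    tau: float, omega_eff: float, zeta_r: float, zeta_eff: float
) -> tuple[float, float]:
    """Nominal efficiency epsilon(tau) and its bound zeta_r/(4 zeta_eff).

    epsilon(tau) = (omega_eff - tau/zeta_r) * tau / (zeta_eff * omega_eff^2),
    a downward parabola in tau with maximum at tau* = zeta_r*omega_eff/2.
    """
    if zeta_eff <= 0:
        raise ValueError("zeta_eff must be > 0")
    if zeta_r <= 0:
        raise ValueError("zeta_r must be > 0")
    if omega_eff == 0:
        raise ValueError("efficiency undefined at omega_eff = 0")
    eps = (omega_eff - tau / zeta_r) * tau / (zeta_eff * omega_eff**2)
    bound = zeta_r / (4.0 * zeta_eff)
    assert eps <= bound * (1 + 1e-12), "efficiency exceeded its analytic bound"
    return eps, bound


@dataclass(frozen=True)
class MechanicsReport:
    """All motor-mechanics quantities for one operating point."""

    viscosity_pa_s: float | None
    rotor_length_m: float | None
    zeta_r_nms: float
    omega_rad_s: float
    torque_pn_nm: float
    power_pn_nm_s: float
    power_kt_s: float
    atp_per_s: float
    temperature_k: float
    atp_energy_kt: float
    tau_opt_pn_nm: float
    efficiency_bound: float | None
    zeta_eff_nms: float | None

    def to_dict(self) -> dict:
        return asdict(self)


def mechanics_report(
    zeta_r: float | None = None,
    omega_rad_s: float = 25.0,
    viscosity_pa_s: float | None = None,
    rotor_length_m: float | None = None,
    temperature_k: float = 293.0,
    atp_energy_kt: float = 25.0,
    zeta_eff: float | None = None,
) -> MechanicsReport:
    """Assemble a full mechanics report.

    Provide either zeta_r directly or (viscosity, rotor length) for the
    pi*eta*L^3 formula. tau_opt = zeta_r*omega/2 is the torque of maximum
    extractable work on the linear load line.
    """
    if zeta_r is None:
        if viscosity_pa_s is None or rotor_length_m is None:
            raise ValueError("give zeta_r or (viscosity, rotor length)")
        zeta_r = rotational_friction(viscosity_pa_s, rotor_length_m)
    tau = torque_from_speed(zeta_r, omega_rad_s)
    power = dissipated_power(zeta_r, omega_rad_s, temperature_k, atp_energy_kt)
    bound = zeta_r / (4.0 * zeta_eff) if zeta_eff else None
    return MechanicsReport(
        viscosity_pa_s=viscosity_pa_s,
        rotor_length_m=rotor_length_m,
        zeta_r_nms=zeta_r,
        omega_rad_s=omega_rad_s,
        torque_pn_nm=tau,
        power_pn_nm_s=power["power_pn_nm_s"],
        power_kt_s=power["power_kt_s"],
        atp_per_s=power["atp_per_s"],
        temperature_k=temperature_k,
        atp_energy_kt=atp_energy_kt,
        tau_opt_pn_nm=tau / 2.0,
        efficiency_bound=bound,
        zeta_eff_nms=zeta_eff,
    )
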