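"""Plume-rise inversion: rise height + stratification -> vent power and fluid flux.

The Morton-Taylor-Turner (MTT) model for a buoyant plume in a linearly
stratified ambient gives a maximum rise height

    z_max = C * F0^(1/4) * N^(-3/4)

with F0 the source buoyancy flux (m4 s-3), N the buoyancy frequency
(s-1), and C a dimensionless coefficient (default 3.76, the spreading/
neutral-height form common in the hydrothermal literature). Inverting
for F0 and converting through the linear seawater expansion yields the
vent heat flux ("power"); dividing power by the heat content of the
endmember fluid relative to ambient yields the fluid volume flux.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .constants import SeawaterConstants

SECONDS_PER_DAY = 86_400.0


@dataclass(frozen=True)
class VentPower:
    """Derived source terms of one vent, with the assumptions that produced them."""

    buoyancy_flux_F0: float  # m4 s-3
    power_W: float
    volume_flux_m3_per_day: float
    assumptions: dict = field(default_factory=dict)


def buoyancy_flux_from_rise(
    z_max_m: float, N_per_s: float, constants: SeawaterConstants = SeawaterConstants()
) -> float:
    """Source buoyancy flux F0 (m4 s-3) from observed maximum rise height.

    Inverse of the MTT rise relation: F0 = (z_max / C)^4 * N^3.
    """
    if z_max_m <= 0:
        raise ValueError("rise height must be positive")
    if N_per_s <= 0:
        raise ValueError("N must be positive: unstratified water has no finite rise height")
    return (z_max_m / constants.mtt_coefficient) ** 4 * N_per_s**3


def rise_height_from_buoyancy_flux(
    F0: float, N_per_s: float, constants: SeawaterConstants = SeawaterConstants()
) -> float:
    """Forward MTT relation z_max = C * F0^(1/4) * N^(-3/4); inverse of the above."""
    if F0 < 0 or N_per_s <= 0:
        raise ValueError("need F0 >= 0 and N > 0")
    return constants.mtt_coefficient * F0**0.25 * N_per_s**-0.75


def power_from_buoyancy_flux(
    F0: float, constants: SeawaterConstants = SeawaterConstants()
) -> float:
    """Vent heat flux P (W) from buoyancy flux: P = F0 * rho * cp / (g * alpha)."""
    if F0 < 0:
        raise ValueError("buoyancy flux must be non-negative")
    return F0 * constants.rho * constants.cp / (constants.g * constants.alpha)


def volume_flux_from_power(
    power_W: float,
    T_endmember_C: float,
    T_ambient_C: float,
    constants: SeawaterConstants = SeawaterConstants(),
) -> float:
    """Endmember fluid volume flux (m3 per day) carrying the vent's heat.

    Q = P / (rho * cp * dT) * 86400, with dT the endmember-minus-ambient
    temperature difference in kelvin.
    """
    if power_W < 0:
        raise ValueError("power must be non-negative")
    dT = T_endmember_C - T_ambient_C
    if dT <= 0:
        raise ValueError("endmember must be warmer than ambient (dT > 0)")
    return power_W / (constants.rho * constants.cp * dT) * SECONDS_PER_DAY


def vent_power_from_observations(
    z_max_m: float,
    N_per_s: float,
    T_endmember_C: float,
    T_ambient_C: float,
    constants: SeawaterConstants = SeawaterConstants(),
) -> VentPower:
    """Full inversion chain: rise height and N -> F0 -> power -> volume flux."""
    F0 = buoyancy_flux_from_rise(z_max_m, N_per_s, constants)
    P = power_from_buoyancy_flux(F0, constants)
    Q = volume_flux_from_power(P, T_endmember_C, T_ambient_C, constants)
    return VentPower(
        buoyancy_flux_F0=F0,
        power_W=P,
        volume_flux_m3_per_day=Q,
        assumptions={
            **constants.as_dict(),
            "z_max_m": z_max_m,
            "N_per_s": N_per_s,
            "T_endmember_C": T_endmember_C,
            "T_ambient_C": T_ambient_C,
        },
    )
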