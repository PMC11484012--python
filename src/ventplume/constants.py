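"""Physical constants and unit conversions shared across the pipeline.

All temperatures are accepted in degrees Celsius at module interfaces;
temperature *differences* are in kelvin. Depths are meters below sea
level, positive downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

#: Disintegrations per minute per becquerel.
DPM_PER_BQ = 60.0

#: Days per year used for annual flux conversions.
DAYS_PER_YEAR = 365.25

#: Molar masses (g/mol) of the species tracked in vent flux budgets.
MOLAR_MASS_G_PER_MOL: dict[str, float] = {
    "ch4": 16.043,
    "h2": 2.016,
    "fe": 55.845,
    "mn": 54.938,
    "sulfide": 34.08,
}

#: Dimensionless water/gas solubility (Ostwald-type, C_aq/C_gas) near 20 degC,
#: the bench temperature at which shaken incubation bottles are subsampled.
HENRY_DIMENSIONLESS_20C: dict[str, float] = {
    "h2": 0.019,
    "ch4": 0.034,
}


@dataclass(frozen=True)
class SeawaterConstants:
    """Bulk seawater properties used by the plume-rise inversion.

    Defaults are deep polar-ocean values: density ``rho`` and heat
    capacity ``cp`` reproduce the canonical heat-to-volume-flux
    conversion for a black-smoker endmember; ``mtt_coefficient`` is the
    maximum-rise-height coefficient of the Morton-Taylor-Turner plume
    model, z_max = C * F0^(1/4) * N^(-3/4).
    """

    rho: float = 1028.0  # kg m-3
    cp: float = 3900.0  # J kg-1 K-1
    g: float = 9.81  # m s-2
    alpha: float = 1.0e-4  # K-1, thermal expansion
    mtt_coefficient: float = 3.76  # dimensionless

    def __post_init__(self) -> None:
        for name in ("rho", "cp", "g", "alpha", "mtt_coefficient"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SeawaterConstants.{name} must be strictly positive")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)
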