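"""Endmember reconstruction and vent flux budgets from Niskin bottle chemistry.

Heat is treated as a conservative tracer: the ratio of the endmember
temperature excess to the in-plume temperature anomaly measured at
bottle closure is the dilution factor of vent fluid in the sample.
Scaling the background-corrected plume concentration of a species by
that dilution reconstructs its concentration in the undiluted endmember
fluid; multiplying by the fluid volume flux gives daily molar emissions
and, with the molar mass, annual tonnages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .constants import DAYS_PER_YEAR, MOLAR_MASS_G_PER_MOL

WATER_TYPES = {"plume", "buoyant_plume", "above_plume", "below_plume", "reference"}

BOTTLE_COLUMNS = [
    "sample_id",
    "cast_id",
    "depth_m",
    "water_type",
    "delta_T_mK",
    "ch4_nM",
    "h2_nM",
    "d3He_percent",
    "fe_nM",
    "mn_nM",
]


def read_bottles_csv(path: str | Path) -> pd.DataFrame:
    """Read a Niskin bottle table, validating water types and sign constraints."""
    df = pd.read_csv(path)
    return validate_bottles(df)


def validate_bottles(df: pd.DataFrame) -> pd.DataFrame:
    bad = set(df["water_type"]) - WATER_TYPES
    if bad:
        raise ValueError(f"unknown water_type values: {sorted(bad)}")
    for col in ("ch4_nM", "h2_nM", "fe_nM", "mn_nM"):
        if col in df.columns and (df[col].dropna() < 0).any():
            raise ValueError(f"negative concentrations in column {col}")
    plume = df[df["water_type"] == "plume"]
    if "delta_T_mK" in df.columns and (plume["delta_T_mK"].dropna() < 0).any():
        raise ValueError("plume samples must have non-negative temperature anomalies")
    return df


def dilution_factor(T_endmember_C: float, T_ambient_C: float, delta_T_mK: float) -> float:
    """Dilution of vent fluid in a plume sample from its temperature anomaly.

    D = (T_end - T_amb) / (delta_T in K). A 30 mK anomaly against a
    270 degC endmember in -0.8 degC ambient water gives D ~ 9000.
    """
    return dilution_factor_from_excess(T_endmember_C - T_ambient_C, delta_T_mK)


def dilution_factor_from_excess(temperature_excess_K: float, delta_T_mK: float) -> float:
    """Dilution from the endmember temperature excess directly (in kelvin)."""
    if delta_T_mK <= 0:
        raise ValueError(
            "temperature anomaly must be positive: at delta_T <= 0 the dilution is unbounded"
        )
    if temperature_excess_K <= 0:
        raise ValueError("endmember temperature excess must be positive")
    return temperature_excess_K / (delta_T_mK * 1e-3)


def endmember_concentration(
    plume_conc_nM: float, background_conc_nM: float, dilution: float
) -> float:
    """Endmember concentration (mM) from background-corrected plume excess.

    endmember_mM = (plume - background) nM * dilution * 1e-6.
    """
    if dilution < 1:
        raise ValueError("dilution factor must be >= 1")
    excess = plume_conc_nM - background_conc_nM
    if excess < 0:
        raise ValueError("plume concentration below background: no enrichment to project")
    return excess * dilution * 1e-6


def species_daily_flux(volume_flux_m3_per_day: float, endmember_mM: float) -> float:
    """Daily molar emission (mol/d): Q (m3/d) x endmember (mM = mol/m3)."""
    if volume_flux_m3_per_day < 0 or endmember_mM < 0:
        raise ValueError("volume flux and endmember concentration must be non-negative")
    return volume_flux_m3_per_day * endmember_mM


def annual_mass_flux(daily_mol_flux: float, molar_mass_g_per_mol: float) -> float:
    """Annual emission in metric tons: mol/d x 365.25 d/yr x M g/mol / 1e6 g/t."""
    if daily_mol_flux < 0 or molar_mass_g_per_mol <= 0:
        raise ValueError("need non-negative flux and positive molar mass")
    return daily_mol_flux * DAYS_PER_YEAR * molar_mass_g_per_mol / 1e6


def endmember_ratio(h2_mM: float, ch4_mM: float) -> float:
    """Molar H2:CH4 ratio of the endmember fluid."""
    if ch4_mM == 0:
        raise ZeroDivisionError("CH4 endmember is zero; ratio undefined")
    return h2_mM / ch4_mM


def impute_h2_endmember(ch4_mM: float, ratio: float = 10.0) -> float:
    """Assumed H2 endmember when unmeasured: ratio x CH4.

    High-temperature black-smoker fluids typically carry a molar H2:CH4
    ratio of ~10 or more; callers should flag the result as assumed.
    """
    return ratio * ch4_mM


@dataclass(frozen=True)
class EndmemberEstimate:
    """One species' reconstructed endmember and the inputs used."""

    species: str
    plume_conc_nM: float
    background_conc_nM: float
    dilution: float
    endmember_mM: float
    assumed: bool = False  # True when imputed from a ratio, not measured

    def __post_init__(self) -> None:
        if self.dilution < 1:
            raise ValueError("dilution must be >= 1")


@dataclass
class FluxBudget:
    """Per-vent daily molar and annual mass fluxes for each species."""

    volume_flux_m3_per_day: float
    daily_mol_per_day: dict[str, float] = field(default_factory=dict)
    annual_tons_per_year: dict[str, float] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def estimate_endmembers(
    bottles: pd.DataFrame,
    T_endmember_C: float,
    T_ambient_C: float,
    species: Iterable[str] = ("ch4", "h2", "fe", "mn"),
    background: str = "reference_mean",
    aggregate: str = "median",
) -> dict[str, EndmemberEstimate]:
    """Reconstruct endmember concentrations from a bottle table.

    Per plume sample, a dilution factor from its temperature anomaly and
    an endmember projection of the background-corrected concentration;
    aggregated across samples by the median (``aggregate='median'``, the
    default — robust to the strongly right-skewed dilution distribution)
    or by projecting the single most concentrated sample at the minimum
    dilution with zero background (``aggregate='max'``, the convention
    of shipboard first-look estimates).

    ``background`` is ``'reference_mean'`` (mean over reference-water
    samples, the conservative-mixing-correct choice) or ``'zero'``.
    """
    bottles = validate_bottles(bottles)
    plume = bottles[bottles["water_type"] == "plume"]
    ref = bottles[bottles["water_type"] == "reference"]
    out: dict[str, EndmemberEstimate] = {}
    for sp in species:
        col = f"{sp}_nM"
        if col not in bottles.columns or plume[col].dropna().empty:
            continue
        if background == "reference_mean" and not ref.empty and ref[col].notna().any():
            bg = float(ref[col].mean())
        else:
            bg = 0.0
        rows = plume[[col, "delta_T_mK"]].dropna()
        rows = rows[rows["delta_T_mK"] > 0]
        if rows.empty:
            continue
        D = (T_endmember_C - T_ambient_C) / (rows["delta_T_mK"].to_numpy() * 1e-3)
        if aggregate == "max":
            i = int(np.argmax(rows[col].to_numpy()))
            d_use = float(D.min())
            c_use = float(rows[col].to_numpy().max())
            em = endmember_concentration(c_use, 0.0 if background == "zero" else bg, d_use)
            out[sp] = EndmemberEstimate(sp, c_use, bg if background != "zero" else 0.0, d_use, em)
        else:
            excess = np.clip(rows[col].to_numpy() - bg, 0.0, None)
            ems = excess * D * 1e-6
            out[sp] = EndmemberEstimate(
                sp,
                float(np.median(rows[col])),
                bg,
                float(np.median(D)),
                float(np.median(ems)),
            )
    return out


def flux_budget(
    endmembers: Mapping[str, float | EndmemberEstimate],
    volume_flux_m3_per_day: float,
    molar_masses: Mapping[str, float] = MOLAR_MASS_G_PER_MOL,
) -> FluxBudget:
    """Daily molar and annual mass fluxes for every species with an endmember."""
    budget = FluxBudget(volume_flux_m3_per_day=volume_flux_m3_per_day)
    for sp, em in endmembers.items():
        em_mM = em.endmember_mM if isinstance(em, EndmemberEstimate) else float(em)
        daily = species_daily_flux(volume_flux_m3_per_day, em_mM)
        budget.daily_mol_per_day[sp] = daily
        if sp in molar_masses:
            budget.annual_tons_per_year[sp] = annual_mass_flux(daily, molar_masses[sp])
        budget.provenance[sp] = {"endmember_mM": em_mM}
    return budget
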