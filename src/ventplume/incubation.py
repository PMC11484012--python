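"""Sealed-bottle incubation kinetics: headspace conversion and consumption rates.

Serum bottles (256 mL, sealed headspace-free) are amended with dissolved
H2/CH4 and incubated at in-situ temperature; at each time point a subset
of bottles receives a small synthetic-air headspace (24.1 mL, 1 mmol),
is shaken to strip the dissolved gas, and the headspace mixing ratio is
measured by gas chromatography. Concentration time courses across
destructively sampled bottles yield consumption rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import HENRY_DIMENSIONLESS_20C

INCUBATION_WATER_TYPES = {"reference", "buoyant_plume", "nonbuoyant_plume"}


@dataclass
class IncubationSeries:
    """Replicate time-course measurements of one gas in one experiment.

    ``data`` columns: bottle_id, time_d and one (or both) of ppmv / nM.
    Geometry defaults match the shipboard protocol: 256-mL bottles with
    a 24.1-mL (1 mmol) headspace; water volume is bottle minus headspace.
    """

    experiment_id: str
    water_type: str
    gas: str  # "h2" | "ch4"
    data: pd.DataFrame
    bottle_volume_mL: float = 256.0
    headspace_volume_mL: float = 24.1
    headspace_moles: float = 1.0e-3

    def __post_init__(self) -> None:
        if self.water_type not in INCUBATION_WATER_TYPES:
            raise ValueError(f"unknown water_type {self.water_type!r}")
        if (self.data["time_d"] < 0).any():
            raise ValueError("incubation times must be non-negative")
        if self.bottle_volume_mL <= self.headspace_volume_mL:
            raise ValueError("water volume (bottle - headspace) must be positive")

    @property
    def water_volume_L(self) -> float:
        return (self.bottle_volume_mL - self.headspace_volume_mL) / 1000.0

    def concentrations_nM(self, mode: str = "complete", temperature_C: float = 20.0) -> pd.DataFrame:
        """time/concentration pairs, converting ppmv rows where nM is absent."""
        df = self.data.copy()
        if "nM" not in df.columns:
            df["nM"] = np.nan
        if "ppmv" in df.columns:
            need = df["nM"].isna() & df["ppmv"].notna()
            df.loc[need, "nM"] = [
                headspace_to_dissolved(
                    p,
                    water_volume_L=self.water_volume_L,
                    headspace_moles=self.headspace_moles,
                    headspace_volume_mL=self.headspace_volume_mL,
                    gas=self.gas,
                    temperature_C=temperature_C,
                    mode=mode,
                )
                for p in df.loc[need, "ppmv"]
            ]
        out = df[["time_d", "nM"]].dropna().reset_index(drop=True)
        if out.empty:
            raise ValueError(f"experiment {self.experiment_id}: no usable concentrations")
        return out


@dataclass(frozen=True)
class RateEstimate:
    """Fitted consumption of one experiment."""

    experiment_id: str
    water_type: str
    gas: str
    model: str  # "zero_order" | "first_order"
    rate: float  # nM/d (zero order) or k in 1/d (first order)
    se: float
    c0: float  # fitted initial concentration, nM
    verdict: str  # "consumed" | "stable"
    r_squared: float
    p_value: float  # one-sided, H1: concentration declines


def headspace_to_dissolved(
    ppmv: float,
    water_volume_L: float = (256.0 - 24.1) / 1000.0,
    headspace_moles: float = 1.0e-3,
    headspace_volume_mL: float = 24.1,
    gas: str = "h2",
    temperature_C: float = 20.0,
    mode: str = "complete",
) -> float:
    """Convert a headspace mixing ratio (ppmv) to dissolved concentration (nM).

    ``complete`` mode (default) assumes vigorous shaking transferred all
    dissolved gas into the headspace: nM = ppmv*1e-6 * n_headspace /
    V_water * 1e9. ``henry`` mode additionally credits the fraction
    still dissolved at equilibrium via the dimensionless solubility
    H_cc = C_aq/C_gas at the shaking temperature, multiplying by
    (1 + H_cc * V_water / V_headspace).
    """
    if ppmv < 0:
        raise ValueError("mixing ratio cannot be negative")
    if water_volume_L <= 0:
        raise ValueError("water volume must be positive")
    n_head = ppmv * 1e-6 * headspace_moles  # mol in headspace
    if mode == "henry":
        try:
            h_cc = HENRY_DIMENSIONLESS_20C[gas]
        except KeyError:
            raise ValueError(f"no solubility constant for gas {gas!r}") from None
        # temperature dependence over the narrow bench range is below
        # measurement precision; the 20 degC constant is used as-is
        n_total = n_head * (1.0 + h_cc * water_volume_L * 1000.0 / headspace_volume_mL)
    elif mode == "complete":
        n_total = n_head
    else:
        raise ValueError(f"unknown conversion mode {mode!r}")
    return n_total / water_volume_L * 1e9


def dissolved_to_headspace(
    nM: float,
    water_volume_L: float = (256.0 - 24.1) / 1000.0,
    headspace_moles: float = 1.0e-3,
) -> float:
    """Forward model of the complete-transfer conversion (nM -> ppmv)."""
    return nM * 1e-9 * water_volume_L / headspace_moles * 1e6


def fit_consumption(
    series: IncubationSeries,
    model: str = "zero_order",
    alpha: float = 0.05,
    mode: str = "complete",
) -> RateEstimate:
    """Estimate gas consumption from a bottle time course.

    ``zero_order``: OLS of concentration vs time, rate = -slope (nM/d).
    ``first_order``: OLS of log concentration vs time, k = -slope (1/d).
    Bottles are destructively sampled, so observations are independent;
    the verdict is "consumed" only when the decline is significant
    (one-sided t on the slope at ``alpha``).
    """
    conc = series.concentrations_nM(mode=mode)
    if conc["time_d"].nunique() < 2:
        raise ValueError("need at least 2 distinct time points")
    t = conc["time_d"].to_numpy(dtype=float)
    c = conc["nM"].to_numpy(dtype=float)
    if model == "zero_order":
        y = c
    elif model == "first_order":
        if (c <= 0).all():
            raise ValueError("all concentrations are zero; log-linear fit undefined")
        keep = c > 0
        t, y = t[keep], np.log(c[keep])
    else:
        raise ValueError(f"unknown model {model!r}")
    fit = stats.linregress(t, y)
    dof = len(t) - 2
    if fit.stderr > 0 and dof > 0:
        p_one = stats.t.cdf(fit.slope / fit.stderr, dof)  # H1: slope < 0
    else:
        p_one = 0.0 if fit.slope < 0 else 1.0
    c0 = float(np.exp(fit.intercept)) if model == "first_order" else float(fit.intercept)
    return RateEstimate(
        experiment_id=series.experiment_id,
        water_type=series.water_type,
        gas=series.gas,
        model=model,
        rate=float(-fit.slope),
        se=float(fit.stderr),
        c0=c0,
        verdict="consumed" if p_one < alpha else "stable",
        r_squared=float(fit.rvalue**2),
        p_value=float(p_one),
    )


def experiment_summary(estimates: Sequence[RateEstimate]) -> dict:
    """Aggregate verdicts and rates over an ensemble of incubation experiments.

    Counts consumed/stable per water type and averages the zero-order
    rate over the consuming experiments (nM/d, numerically identical to
    umol m-3 d-1).
    """
    counts: dict[str, dict[str, int]] = {}
    consuming_rates = []
    for est in estimates:
        wt = counts.setdefault(est.water_type, {"consumed": 0, "stable": 0})
        wt[est.verdict] += 1
        if est.verdict == "consumed" and est.model == "zero_order":
            consuming_rates.append(est.rate)
    return {
        "counts_by_water_type": counts,
        "n_consumed": sum(c["consumed"] for c in counts.values()),
        "n_experiments": len(estimates),
        "mean_consumption_rate_umol_m3_d": float(np.mean(consuming_rates))
        if consuming_rates
        else None,
    }


def read_incubations_csv(path: str | Path) -> list[IncubationSeries]:
    """Read incubation series from CSV.

    Columns: experiment_id, water_type, gas, bottle_id, time_d and one of
    ppmv / nM; optional geometry overrides bottle_volume_mL,
    headspace_volume_mL, headspace_moles (constant per experiment).
    """
    df = pd.read_csv(path)
    out = []
    for (eid, wt, gas), grp in df.groupby(["experiment_id", "water_type", "gas"], sort=False):
        kwargs = {}
        for col in ("bottle_volume_mL", "headspace_volume_mL", "headspace_moles"):
            if col in grp.columns and grp[col].notna().any():
                kwargs[col] = float(grp[col].iloc[0])
        cols = [c for c in ("bottle_id", "time_d", "ppmv", "nM") if c in grp.columns]
        out.append(
            IncubationSeries(
                experiment_id=str(eid),
                water_type=str(wt),
                gas=str(gas),
                data=grp[cols].reset_index(drop=True),
                **kwargs,
            )
        )
    return out
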