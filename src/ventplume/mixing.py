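"""Conservative-tracer mixing diagnostics for plume gases.

A gas that is only diluted (not consumed) stays proportional to a
biologically inert vent tracer — delta-3He or, at these scales, CH4 —
across the whole dilution range of the plume. Microbial consumption
shows up as concentrations at high dilution (low tracer) falling below
the mixing line anchored in the most concentrated samples, and as a
decline of the gas:tracer ratio along the dilution gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class MixingReport:
    """Regression-based conservativity assessment of one species/tracer pair."""

    species: str
    tracer: str
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r: float
    n: int
    conservative: bool
    consumed: bool
    deviation_statistic: float  # one-sided t statistic of low-tracer shortfall
    deviation_p: float
    intercept_p: float

    def verdict(self) -> str:
        return "consumed" if self.consumed else ("conservative" if self.conservative else "ambiguous")


@dataclass
class RatioSeries:
    """Gas ratio ordered along the dilution gradient, with a trend statistic."""

    numerator: str
    denominator: str
    dilution_index: str
    table: pd.DataFrame  # columns: dilution index, ratio; sorted by decreasing index
    kendall_tau: float
    kendall_p: float
    n_dropped_zero_denominator: int


def _paired(samples: pd.DataFrame, a: str, b: str, exclude_buoyant: bool) -> pd.DataFrame:
    df = samples
    if exclude_buoyant and "water_type" in df.columns:
        # the buoyant stem rises in ~an hour: consumption is not yet expressed there
        df = df[df["water_type"] != "buoyant_plume"]
    return df[[a, b]].dropna().reset_index(drop=True)


def conservative_regression(
    samples: pd.DataFrame,
    species: str,
    tracer: str,
    background_conc: float = 0.0,
    alpha: float = 0.05,
    exclude_buoyant: bool = True,
) -> MixingReport:
    """OLS of species vs tracer with a tercile-anchored consumption test.

    The full-data fit gives slope/intercept/r. "Conservative" means the
    intercept is statistically indistinguishable from the background
    concentration (two-sided t at ``alpha``). "Consumed" means the
    observations in the lowest-tracer tercile fall significantly below
    the line fitted to the highest-tracer tercile only — that line is
    anchored at the vent end of the mixing series, where consumption has
    had the least time to act.
    """
    df = _paired(samples, species, tracer, exclude_buoyant)
    if len(df) < 4:
        raise ValueError("need at least 4 samples with both quantities")
    x = df[tracer].to_numpy(dtype=float)
    y = df[species].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("tracer has zero variance; mixing line undefined")

    fit = stats.linregress(x, y)
    dof = len(x) - 2
    if fit.intercept_stderr > 0:
        t_int = (fit.intercept - background_conc) / fit.intercept_stderr
        p_int = 2 * stats.t.sf(abs(t_int), dof)
    else:
        p_int = 1.0 if np.isclose(fit.intercept, background_conc) else 0.0
    conservative = p_int > alpha

    t_stat, p_dev = _tercile_shortfall(x, y, background_conc)
    consumed = p_dev < alpha

    return MixingReport(
        species=species,
        tracer=tracer,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        slope_se=float(fit.stderr),
        intercept_se=float(fit.intercept_stderr),
        r=float(fit.rvalue),
        n=len(x),
        conservative=bool(conservative),
        consumed=bool(consumed),
        deviation_statistic=float(t_stat),
        deviation_p=float(p_dev),
        intercept_p=float(p_int),
    )


def _tercile_shortfall(
    x: np.ndarray, y: np.ndarray, background: float
) -> tuple[float, float]:
    """One-sided test that low-tracer points fall below the vent-anchored line.

    A conservative mixing line must pass through the background
    concentration at zero tracer, so each tercile of the data defines a
    vent-anchored slope by the ratio estimator R = sum(y - background) /
    sum(x). Under pure dilution R is the same everywhere; consumption
    pulls R down in the most dilute (lowest-tracer) tercile. The
    statistic contrasts R_low against R_high (the vent end, least
    affected by consumption) with ratio-estimator variances, which grow
    without bound as the tercile's tracer signal vanishes — so noise-
    dominated near-background samples cannot fake a shortfall. Returns
    (t, one-sided p toward shortfall; Welch-Satterthwaite dof).
    """
    keep = x > 0
    x, y = x[keep], y[keep]
    if len(x) < 6:
        return 0.0, 1.0
    order = np.argsort(x)
    third = max(3, len(x) // 3)

    def ratio_and_var(idx: np.ndarray) -> tuple[float, float, int]:
        xs, ys = x[idx], y[idx] - background
        R = ys.sum() / xs.sum()
        e = ys - R * xs
        n = len(idx)
        var = (n / (n - 1)) * float(e @ e) / xs.sum() ** 2
        return float(R), var, n

    R_lo, v_lo, n_lo = ratio_and_var(order[:third])
    R_hi, v_hi, n_hi = ratio_and_var(order[-third:])
    se = np.sqrt(v_lo + v_hi)
    if se == 0:
        return 0.0, 1.0
    t_stat = float((R_lo - R_hi) / se)
    dof = (v_lo + v_hi) ** 2 / (v_lo**2 / (n_lo - 1) + v_hi**2 / (n_hi - 1))
    p = stats.t.cdf(t_stat, dof)  # shortfall = dilute-end slope significantly smaller
    return t_stat, float(p)


def ratio_vs_dilution(
    samples: pd.DataFrame,
    numerator: str,
    denominator: str,
    dilution_index: str = "d3He_percent",
    exclude_buoyant: bool = True,
) -> RatioSeries:
    """Gas ratio series ordered from most- to least-concentrated samples.

    Higher values of the dilution index (delta-3He by default; CH4 or
    the temperature anomaly are alternatives) mark less dilute plume
    water. Samples with zero denominator are dropped and counted. A
    Kendall tau between ratio and index quantifies the monotone trend:
    significantly positive tau means the ratio declines with dilution,
    the signature of numerator consumption.
    """
    cols = [numerator, denominator, dilution_index]
    df = samples
    if exclude_buoyant and "water_type" in df.columns:
        df = df[df["water_type"] != "buoyant_plume"]
    df = df[cols].dropna()
    if df.empty or (df[denominator] > 0).sum() == 0:
        raise ValueError("no samples with positive denominator")
    n_dropped = int((df[denominator] <= 0).sum())
    df = df[df[denominator] > 0].copy()
    df["ratio"] = df[numerator] / df[denominator]
    df = df.sort_values(dilution_index, ascending=False, kind="mergesort").reset_index(drop=True)
    if df["ratio"].nunique() > 1 and df[dilution_index].nunique() > 1:
        tau, p = stats.kendalltau(df[dilution_index], df["ratio"])
    else:
        tau, p = 0.0, 1.0
    return RatioSeries(
        numerator=numerator,
        denominator=denominator,
        dilution_index=dilution_index,
        table=df[[dilution_index, "ratio"]],
        kendall_tau=float(tau),
        kendall_p=float(p),
        n_dropped_zero_denominator=n_dropped,
    )
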