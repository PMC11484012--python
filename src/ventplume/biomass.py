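"""Chemosynthetic biomass budget: rates -> cell growth and energy attribution.

Converts dark CO2 fixation rates into potential cell yields using a
fixed per-cell carbon quota, translates hydrogen oxidation rates into
the carbon fixation they can support through an empirical growth
efficiency, and attributes the observed plume fixation to the hydrogen
energy source.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BudgetParams:
    """Conversion factors of the biomass budget.

    cell_carbon_quota_mol: carbon content of one plume cell (default
    1e-14 mol = 10 fmol, typical of small chemolithoautotrophs).
    h2_growth_efficiency: fraction of oxidized H2 (mole basis) fixed as
    carbon; up to 0.25 for aerobic hydrogen oxidizers.
    """

    cell_carbon_quota_mol: float = 1e-14
    h2_growth_efficiency: float = 0.25
    background_cell_density_per_m3: float | None = None

    def __post_init__(self) -> None:
        if self.cell_carbon_quota_mol <= 0:
            raise ValueError("cell carbon quota must be positive")
        if not 0 < self.h2_growth_efficiency <= 1:
            raise ValueError("growth efficiency must be in (0, 1]")


def cells_from_fixation(
    dcf_rate_umol_m3_d: float, params: BudgetParams = BudgetParams()
) -> float:
    """Potential cell growth (cells m-3 d-1) supported by a fixation rate."""
    if dcf_rate_umol_m3_d < 0:
        raise ValueError("fixation rate must be non-negative")
    return dcf_rate_umol_m3_d * 1e-6 / params.cell_carbon_quota_mol


def h2_supported_fixation(
    h2_rate_umol_m3_d: float, params: BudgetParams = BudgetParams()
) -> float:
    """Carbon fixation (umol C m-3 d-1) supportable by a H2 oxidation rate.

    Mole-for-mole bookkeeping: fixation = H2 rate x efficiency. (H2 and
    CO2 fixation happen to exchange 2 and 4 electrons respectively; an
    electron-balance variant would halve the yield — see
    :func:`h2_supported_fixation_electron_balance`.)
    """
    if h2_rate_umol_m3_d < 0:
        raise ValueError("H2 oxidation rate must be non-negative")
    return h2_rate_umol_m3_d * params.h2_growth_efficiency


def h2_supported_fixation_electron_balance(
    h2_rate_umol_m3_d: float, params: BudgetParams = BudgetParams()
) -> float:
    """Electron-balance variant: 2 e- per H2, 4 e- per C fixed.

    fixation = H2 rate x efficiency x (2/4). Stricter than the
    mole-basis default; provided for sensitivity analyses.
    """
    return h2_supported_fixation(h2_rate_umol_m3_d, params) * 0.5


def fixation_attribution(
    h2_supported_umol_m3_d: float, total_fixation_umol_m3_d: float
) -> tuple[float, bool]:
    """Fraction of total plume fixation attributable to H2 oxidation.

    Returns (fraction, capped): the raw ratio capped at 1 with a flag
    when the supportable fixation exceeds the observed total.
    """
    if total_fixation_umol_m3_d <= 0:
        raise ValueError("total fixation must be positive")
    if h2_supported_umol_m3_d < 0:
        raise ValueError("H2-supported fixation must be non-negative")
    frac = h2_supported_umol_m3_d / total_fixation_umol_m3_d
    return (min(frac, 1.0), frac > 1.0)


def community_increase(
    cells_per_m3_per_day: float, background_cell_density_per_m3: float
) -> float:
    """Daily fractional increase of cell mass relative to the standing stock."""
    if background_cell_density_per_m3 <= 0:
        raise ValueError("background cell density must be positive")
    if cells_per_m3_per_day < 0:
        raise ValueError("cell growth must be non-negative")
    return cells_per_m3_per_day / background_cell_density_per_m3
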