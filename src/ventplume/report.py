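"""End-to-end site report: profiles -> physics -> endmember/flux -> rates -> budget.

A single config (dict or YAML file) names the input tables and site
parameters; :func:`run_pipeline` executes every stage it has inputs for
and assembles a versioned, JSON-serializable report. Stages without
inputs are marked ``"not computed"`` rather than failing, so partial
campaigns still produce partial reports. Reports are regenerable
bit-identically from the same inputs and config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .constants import SeawaterConstants, MOLAR_MASS_G_PER_MOL
from . import ctd as ctd_mod
from . import physics, endmember, mixing, radiotracer, incubation, biomass

SCHEMA_VERSION = 1
NOT_COMPUTED = "not computed"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: dict, base_dir: str | Path = ".") -> dict:
    """Run every stage the config provides inputs for; return a SiteReport dict.

    Config keys (all optional except ``site``):
      site: name
      t_endmember_C / t_ambient_C: endmember and ambient temperatures
      constants: overrides for SeawaterConstants fields
      casts: {references: [csv...], plume: [csv...], property, bin_width_m,
              k_sd, N_window: [top, bottom]}
      rise_height_m: overrides the delineated rise height for the power inversion
      bottles: csv path (Niskin chemistry)
      mixing: {species, tracer, dilution_index}
      incubations: csv path; dcf_assays / mox_assays: csv paths
      budget: {cell_carbon_quota_fmol, h2_growth_efficiency,
               background_cell_density_per_m3}
    """
    base = Path(base_dir)
    site = config.get("site", "unnamed")
    constants = SeawaterConstants(**config.get("constants", {}))
    t_end = config.get("t_endmember_C")
    t_amb = config.get("t_ambient_C", -0.8)

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "site": site,
        "config": config,
        "provenance": {"input_hashes": {}},
        "plume_geometry": NOT_COMPUTED,
        "power": NOT_COMPUTED,
        "dilution": NOT_COMPUTED,
        "endmember": NOT_COMPUTED,
        "fluxes": NOT_COMPUTED,
        "mixing": NOT_COMPUTED,
        "dcf": NOT_COMPUTED,
        "mox": NOT_COMPUTED,
        "incubations": NOT_COMPUTED,
        "biomass": NOT_COMPUTED,
    }

    def track(path: Path) -> Path:
        report["provenance"]["input_hashes"][str(path)] = _sha256(path)
        return path

    # --- water column ---------------------------------------------------
    N = None
    rise_height = config.get("rise_height_m")
    casts_cfg = config.get("casts")
    if casts_cfg:
        prop = casts_cfg.get("property", "turbidity_NTU")
        refs = [ctd_mod.read_cast_csv(track(base / p)) for p in casts_cfg["references"]]
        bg = ctd_mod.fit_background(refs, prop, casts_cfg.get("bin_width_m", 50.0))
        intervals = []
        for p in casts_cfg.get("plume", []):
            cast = ctd_mod.read_cast_csv(track(base / p))
            anom = ctd_mod.anomaly(cast, bg, prop)
            iv = ctd_mod.delineate_plume(anom, prop, k_sd=casts_cfg.get("k_sd", 3.0))
            if iv is not None:
                intervals.append(iv)
        window = casts_cfg.get("N_window")
        n_cast = refs[0]
        if window is None and intervals:
            window = [min(i.top_depth_m for i in intervals), max(i.bottom_depth_m for i in intervals)]
        if window is not None:
            N = ctd_mod.buoyancy_frequency(n_cast, tuple(window), rho0=constants.rho, g=constants.g)
        seafloor = casts_cfg.get("seafloor_depth_m")
        if intervals:
            top = min(i.top_depth_m for i in intervals)
            geometry = {
                "property": prop,
                "top_depth_m": top,
                "bottom_depth_m": max(i.bottom_depth_m for i in intervals),
                "peak_anomaly": max((i.peak_anomaly for i in intervals), key=abs),
                "N_per_s": N,
            }
            if seafloor is not None and rise_height is None:
                rise_height = seafloor - top
                geometry["rise_height_m"] = rise_height
            report["plume_geometry"] = geometry
        else:
            report["plume_geometry"] = {"property": prop, "interval": None, "N_per_s": N}

    # --- power and volume flux ------------------------------------------
    volume_flux = config.get("volume_flux_m3_per_day")
    if config.get("power_MW") is not None and t_end is not None:
        P = config["power_MW"] * 1e6
        volume_flux = physics.volume_flux_from_power(P, t_end, t_amb, constants)
        report["power"] = {
            "power_W": P,
            "power_MW": P / 1e6,
            "volume_flux_m3_per_day": volume_flux,
            "assumptions": constants.as_dict(),
        }
    elif rise_height is not None and N is not None and N > 0 and t_end is not None:
        vp = physics.vent_power_from_observations(rise_height, N, t_end, t_amb, constants)
        volume_flux = vp.volume_flux_m3_per_day
        report["power"] = asdict(vp) | {"power_MW": vp.power_W / 1e6}

    # --- bottles: dilution, endmember, fluxes, mixing -------------------
    bottles = None
    if config.get("bottles"):
        bottles = endmember.read_bottles_csv(track(base / config["bottles"]))
        if t_end is not None:
            plume_rows = bottles[(bottles["water_type"] == "plume") & (bottles["delta_T_mK"] > 0)]
            if not plume_rows.empty:
                max_dT = float(plume_rows["delta_T_mK"].max())
                report["dilution"] = {
                    "min_dilution": endmember.dilution_factor(t_end, t_amb, max_dT),
                    "max_delta_T_mK": max_dT,
                }
            ems = endmember.estimate_endmembers(
                bottles, t_end, t_amb,
                background=config.get("background_mode", "reference_mean"),
                aggregate=config.get("endmember_aggregate", "median"),
            )
            report["endmember"] = {sp: asdict(e) for sp, e in ems.items()}
            if volume_flux is not None and ems:
                budget = endmember.flux_budget(ems, volume_flux)
                report["fluxes"] = {
                    "volume_flux_m3_per_day": budget.volume_flux_m3_per_day,
                    "daily_mol_per_day": budget.daily_mol_per_day,
                    "annual_tons_per_year": budget.annual_tons_per_year,
                }
        mix_cfg = config.get("mixing", {})
        species = mix_cfg.get("species", "h2_nM")
        tracer = mix_cfg.get("tracer", "d3He_percent")
        try:
            rep = mixing.conservative_regression(bottles, species, tracer)
            report["mixing"] = {
                "species": species,
                "tracer": tracer,
                "slope": rep.slope,
                "intercept": rep.intercept,
                "r": rep.r,
                "verdict": rep.verdict(),
                "deviation_p": rep.deviation_p,
            }
        except ValueError as err:
            report["mixing"] = {"error": str(err)}

    # --- radiotracer rates ----------------------------------------------
    mean_dcf = None
    if config.get("dcf_assays"):
        assays = radiotracer.read_dcf_csv(track(base / config["dcf_assays"]))
        results = [radiotracer.dcf_rate(a) for a in assays]
        rates = [r.rate_umol_m3_d for r in results]
        mean_dcf = sum(rates) / len(rates) if rates else None
        report["dcf"] = {
            "n": len(results),
            "mean_rate_umol_m3_d": mean_dcf,
            "rates": {r.sample_id: r.rate_umol_m3_d for r in results},
        }
    if config.get("mox_assays"):
        assays = radiotracer.read_mox_csv(track(base / config["mox_assays"]))
        results = [radiotracer.mox_rate(a) for a in assays]
        report["mox"] = {
            "n": len(results),
            "n_detected": sum(r.detected for r in results),
            "rates": {r.sample_id: r.rate_umol_m3_d for r in results},
            "turnover_yr": {r.sample_id: (None if r.turnover_time_yr == float("inf") else r.turnover_time_yr) for r in results},
        }

    # --- incubations ------------------------------------------------------
    mean_h2 = None
    if config.get("incubations"):
        series = incubation.read_incubations_csv(track(base / config["incubations"]))
        ests = [incubation.fit_consumption(s, model=config.get("incubation_model", "zero_order")) for s in series]
        summary = incubation.experiment_summary(ests)
        mean_h2 = summary["mean_consumption_rate_umol_m3_d"]
        report["incubations"] = summary | {
            "estimates": [asdict(e) for e in ests],
        }

    # --- biomass budget ---------------------------------------------------
    b_cfg = config.get("budget", {})
    total_fix = b_cfg.get("total_fixation_umol_m3_d", mean_dcf)
    h2_rate = b_cfg.get("h2_oxidation_umol_m3_d", mean_h2)
    if total_fix is not None:
        params = biomass.BudgetParams(
            cell_carbon_quota_mol=b_cfg.get("cell_carbon_quota_fmol", 10.0) * 1e-15,
            h2_growth_efficiency=b_cfg.get("h2_growth_efficiency", 0.25),
            background_cell_density_per_m3=b_cfg.get("background_cell_density_per_m3"),
        )
        cells = biomass.cells_from_fixation(total_fix, params)
        section = {
            "total_fixation_umol_m3_d": total_fix,
            "cells_per_m3_per_day": cells,
        }
        if h2_rate is not None:
            h2_fix = biomass.h2_supported_fixation(h2_rate, params)
            frac, capped = biomass.fixation_attribution(h2_fix, total_fix)
            section |= {
                "h2_oxidation_umol_m3_d": h2_rate,
                "h2_supported_fixation_umol_m3_d": h2_fix,
                "h2_attribution_fraction": frac,
                "h2_attribution_capped": capped,
            }
        if params.background_cell_density_per_m3:
            section["community_increase_per_day"] = biomass.community_increase(
                cells, params.background_cell_density_per_m3
            )
        report["biomass"] = section

    return report


def write_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)


def read_report(path: str | Path) -> dict:
    with open(path) as fh:
        report = json.load(fh)
    if report.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported report schema {report.get('schema_version')!r}")
    return report


def format_report(report: dict) -> str:
    """Human-readable summary table of a SiteReport."""
    lines = [f"Site report: {report['site']} (ventplume {report['package_version']})"]
    for key in ("plume_geometry", "power", "dilution", "endmember", "fluxes",
                "mixing", "dcf", "mox", "incubations", "biomass"):
        val = report.get(key, NOT_COMPUTED)
        if val == NOT_COMPUTED:
            lines.append(f"  {key:16s} {NOT_COMPUTED}")
        else:
            lines.append(f"  {key:16s} {json.dumps(val, default=float)[:160]}")
    return "\n".join(lines)
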