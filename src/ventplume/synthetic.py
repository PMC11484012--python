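"""Synthetic shipboard data with known ground truth.

Generates every input the pipeline consumes — CTD casts, Niskin bottle
chemistry, incubation time courses, and radiotracer assays — from a
:class:`VentScenario` that fixes the endmember fluid, vent power,
stratification, consumption kinetics, and measurement noise. Each
generator returns the data together with a ground-truth ledger dict, so
recovery tests compare against the ledger rather than hard-coded
numbers. Identical scenario + seed yields byte-identical output.

The generator emulates dilution sampling (lognormal dilution factors,
conservative species scaling as 1/D), first-order H2 loss with a plume
age that grows with dilution, Gaussian instrument noise, and Poisson
counting statistics. It does not simulate plume hydrodynamics: dilution is
drawn, not advected, and all samples are exchangeable — real tow-yo
sections have spatial structure this data lacks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ctd import CtdCast
from .incubation import IncubationSeries, dissolved_to_headspace
from .radiotracer import DcfAssay, MoxAssay, ISOTOPE_DISCRIMINATION
from .constants import DPM_PER_BQ

# substream indices: outputs stay stable when one table's size changes
_STREAM_CASTS, _STREAM_BOTTLES, _STREAM_INCUBATIONS, _STREAM_ASSAYS = 1, 2, 3, 4


@dataclass
class NoiseModel:
    """Per-instrument measurement noise (1-sigma unless stated)."""

    ctd_temperature_mK: float = 2.0
    turbidity_NTU: float = 0.02
    eh_mV: float = 2.0
    sigma_density: float = 2.0e-4
    delta_T_mK: float = 0.2
    concentration_cv: float = 0.05
    d3He_percent: float = 0.3
    counting: bool = True  # Poisson statistics on scintillation counts


@dataclass
class VentScenario:
    """Ground truth of one simulated vent site."""

    name: str
    endmember_T_C: float
    composition_mM: dict[str, float]
    power_W: float
    seafloor_depth_m: float
    plume_top_m: float
    plume_bottom_m: float
    d3He_max_percent: float
    min_dilution: float
    ambient_T_C: float = -0.8
    N_per_s: float = 3.5e-4
    h2_consumption_k_per_d: float = 0.0
    plume_age_max_d: float = 7.0
    dilution_log_median: float = 1.0e4
    dilution_log_sigma: float = 0.5
    background_nM: dict[str, float] = field(
        default_factory=lambda: {"ch4": 1.0, "h2": 0.4, "fe": 0.0, "mn": 0.0}
    )
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.endmember_T_C <= 400:
            raise ValueError("endmember temperature must be in (0, 400] degC")
        if any(v < 0 for v in self.composition_mM.values()):
            raise ValueError("endmember composition must be non-negative")
        if self.plume_top_m >= self.plume_bottom_m:
            raise ValueError("plume top must be shallower than plume bottom")

    @property
    def temperature_excess_K(self) -> float:
        return self.endmember_T_C - self.ambient_T_C

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])

    def describe(self) -> dict:
        d = asdict(self)
        d["noise"] = asdict(self.noise)
        return d


def preset(name: str, seed: int = 0, **overrides) -> VentScenario:
    """Built-in site presets mimicking the two studied Gakkel Ridge vents.

    ``polaris``: 270 degC low-metal endmember (2.7 mM CH4, 3.3 mM H2),
    130 MW, delta-3He up to 75%, minimum dilution 9,000, active H2
    consumption in the aged plume.
    ``aurora``: 370 degC black-smoker endmember (1.4 mM CH4, 14 mM H2,
    6.8 mM Fe, 0.7 mM Mn), 24 MW, delta-3He up to 10%, minimum dilution
    45,000, conservative gases.
    """
    presets = {
        "polaris": dict(
            name="polaris",
            endmember_T_C=270.0,
            composition_mM={"ch4": 2.7, "h2": 3.3, "fe": 0.0, "mn": 0.0},
            power_W=130e6,
            seafloor_depth_m=3170.0,
            plume_top_m=2400.0,
            plume_bottom_m=2800.0,
            d3He_max_percent=75.0,
            min_dilution=9000.0,
            h2_consumption_k_per_d=0.5,
        ),
        "aurora": dict(
            name="aurora",
            endmember_T_C=370.0,
            composition_mM={"ch4": 1.4, "h2": 14.0, "fe": 6.8, "mn": 0.7},
            power_W=24e6,
            seafloor_depth_m=3900.0,
            plume_top_m=3100.0,
            plume_bottom_m=3600.0,
            d3He_max_percent=10.0,
            min_dilution=45000.0,
            dilution_log_median=1.0e5,
            h2_consumption_k_per_d=0.0,
        ),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    cfg = presets[name] | overrides
    return VentScenario(seed=seed, **cfg)


def _ramped_block(depth: np.ndarray, top: float, bottom: float, ramp_m: float = 20.0) -> np.ndarray:
    """Unit-amplitude anomaly block: flat inside [top, bottom], cosine ramps outside."""
    shape = np.zeros_like(depth)
    inside = (depth >= top) & (depth <= bottom)
    shape[inside] = 1.0
    above = (depth < top) & (depth > top - ramp_m)
    shape[above] = 0.5 * (1 + np.cos(np.pi * (top - depth[above]) / ramp_m))
    below = (depth > bottom) & (depth < bottom + ramp_m)
    shape[below] = 0.5 * (1 + np.cos(np.pi * (depth[below] - bottom) / ramp_m))
    return shape


def generate_casts(
    scenario: VentScenario,
    n_reference: int = 3,
    n_plume: int = 2,
    dz_m: float = 10.0,
    turbidity_anomaly_NTU: float = 0.3,
    temperature_anomaly_mK: float = 20.0,
    eh_anomaly_mV: float = -25.0,
) -> tuple[list[CtdCast], list[CtdCast], dict]:
    """Reference and plume CTD casts plus the ground-truth ledger.

    Reference casts carry smooth stratified profiles (density gradient
    set by the scenario's N) with instrument noise; plume casts add a
    flat-topped anomaly block with short cosine ramps over the
    scenario's plume interval in turbidity, temperature, and redox.
    """
    rng = scenario.rng(_STREAM_CASTS)
    noise = scenario.noise
    z0 = scenario.plume_top_m - 400.0
    z1 = scenario.seafloor_depth_m - 20.0
    depth = np.arange(z0, z1 + dz_m / 2, dz_m)

    rho0, g = 1028.0, 9.81
    dsigma_ddepth = scenario.N_per_s**2 * rho0 / g  # stable: density grows downward
    sigma_true = 27.80 + dsigma_ddepth * (depth - depth[0])
    temp_true = -0.3 - 0.6 * (depth - depth[0]) / (depth[-1] - depth[0])
    shape = _ramped_block(depth, scenario.plume_top_m, scenario.plume_bottom_m)

    def one_cast(cast_id: str, plume: bool) -> CtdCast:
        t = temp_true + rng.normal(0, noise.ctd_temperature_mK * 1e-3, depth.size)
        turb = 0.10 + rng.normal(0, noise.turbidity_NTU, depth.size)
        eh = rng.normal(0, noise.eh_mV, depth.size)
        sig = sigma_true + rng.normal(0, noise.sigma_density, depth.size)
        if plume:
            t = t + shape * temperature_anomaly_mK * 1e-3
            turb = turb + shape * turbidity_anomaly_NTU
            eh = eh + shape * eh_anomaly_mV
        return CtdCast(
            cast_id=cast_id,
            data=pd.DataFrame(
                {
                    "depth_m": depth,
                    "temperature_C": t,
                    "salinity": np.full(depth.size, 34.90),
                    "sigma": sig,
                    "turbidity_NTU": turb,
                    "eh_offset_mV": eh,
                }
            ),
        )

    references = [one_cast(f"{scenario.name}-ref-{i}", False) for i in range(n_reference)]
    plumes = [one_cast(f"{scenario.name}-plume-{i}", True) for i in range(n_plume)]
    truth = {
        "N_per_s": scenario.N_per_s,
        "plume_top_m": scenario.plume_top_m,
        "plume_bottom_m": scenario.plume_bottom_m,
        "turbidity_anomaly_NTU": turbidity_anomaly_NTU,
        "temperature_anomaly_mK": temperature_anomaly_mK,
        "eh_anomaly_mV": eh_anomaly_mV,
        "turbidity_background_NTU": 0.10,
        "depth_grid_step_m": dz_m,
        "noise": asdict(noise),
        "seed": scenario.seed,
    }
    return references, plumes, truth


def generate_bottles(
    scenario: VentScenario,
    n_plume: int = 30,
    n_reference: int = 8,
) -> tuple[pd.DataFrame, dict]:
    """Niskin bottle table (plume + reference water) and ground-truth ledger.

    Each plume sample draws a dilution factor D from a lognormal
    (median/sigma from the scenario, truncated at the scenario's minimum
    dilution); its temperature anomaly is excess/D, conservative species
    scale as endmember/D plus background plus proportional noise, H2 is
    additionally decayed by exp(-k * age), and delta-3He scales as 1/D
    normalized to the scenario maximum at minimum dilution.

    Plume age grows with dilution (log-linearly from 0 at the minimum
    dilution to the scenario maximum age, plus jitter): dilute plume
    water is old plume water, which is what lets microbial H2 loss
    express itself as a decline of H2 against conservative tracers.
    """
    rng = scenario.rng(_STREAM_BOTTLES)
    noise = scenario.noise

    # rejection-sample the truncated lognormal
    mu = np.log(scenario.dilution_log_median)
    D = np.empty(0)
    while D.size < n_plume:
        draw = rng.lognormal(mu, scenario.dilution_log_sigma, size=4 * n_plume)
        D = np.concatenate([D, draw[draw >= scenario.min_dilution]])
    D = D[:n_plume]
    # age ~ entrainment history: 3 sigma_log of extra dilution spans the full age range
    age_frac = np.clip(
        np.log(D / scenario.min_dilution) / (3.0 * scenario.dilution_log_sigma), 0.0, 1.0
    )
    ages = np.clip(
        age_frac * scenario.plume_age_max_d + rng.normal(0.0, 0.3, n_plume),
        0.0,
        scenario.plume_age_max_d,
    )

    excess = scenario.temperature_excess_K
    rows: dict[str, list] = {c: [] for c in (
        "sample_id", "cast_id", "depth_m", "water_type", "delta_T_mK",
        "ch4_nM", "h2_nM", "d3He_percent", "fe_nM", "mn_nM",
    )}

    def conc(species: str, d: float, decay: float = 1.0) -> float:
        em = scenario.composition_mM.get(species, 0.0)
        true = em / d * 1e6 * decay + scenario.background_nM.get(species, 0.0)
        return max(0.0, true * (1 + rng.normal(0, noise.concentration_cv)))

    plume_depths = rng.uniform(scenario.plume_top_m, scenario.plume_bottom_m, n_plume)
    for i in range(n_plume):
        d = float(D[i])
        decay = float(np.exp(-scenario.h2_consumption_k_per_d * ages[i]))
        dT = excess / d * 1e3 + rng.normal(0, noise.delta_T_mK)
        rows["sample_id"].append(f"{scenario.name}-P{i:03d}")
        rows["cast_id"].append(f"{scenario.name}-plume-0")
        rows["depth_m"].append(round(float(plume_depths[i]), 1))
        rows["water_type"].append("plume")
        rows["delta_T_mK"].append(max(dT, 0.05))
        rows["ch4_nM"].append(conc("ch4", d))
        rows["h2_nM"].append(conc("h2", d, decay))
        he = scenario.d3He_max_percent * scenario.min_dilution / d
        rows["d3He_percent"].append(max(0.0, he + rng.normal(0, noise.d3He_percent)))
        rows["fe_nM"].append(conc("fe", d))
        rows["mn_nM"].append(conc("mn", d))

    for i in range(n_reference):
        rows["sample_id"].append(f"{scenario.name}-R{i:03d}")
        rows["cast_id"].append(f"{scenario.name}-ref-0")
        rows["depth_m"].append(round(float(rng.uniform(scenario.plume_top_m - 300, scenario.seafloor_depth_m - 50)), 1))
        rows["water_type"].append("reference")
        rows["delta_T_mK"].append(0.0)
        for sp in ("ch4", "h2", "fe", "mn"):
            bg = scenario.background_nM.get(sp, 0.0)
            rows[f"{sp}_nM"].append(max(0.0, bg * (1 + rng.normal(0, noise.concentration_cv))))
        rows["d3He_percent"].append(max(0.0, rng.normal(0, noise.d3He_percent)))

    table = pd.DataFrame(rows)
    truth = {
        "endmember_mM": dict(scenario.composition_mM),
        "temperature_excess_K": excess,
        "endmember_T_C": scenario.endmember_T_C,
        "ambient_T_C": scenario.ambient_T_C,
        "background_nM": dict(scenario.background_nM),
        "h2_consumption_k_per_d": scenario.h2_consumption_k_per_d,
        "dilutions": D.tolist(),
        "ages_d": ages.tolist(),
        "min_dilution": scenario.min_dilution,
        "d3He_max_percent": scenario.d3He_max_percent,
        "seed": scenario.seed,
    }
    return table, truth


#: Default incubation campaign: stable reference and buoyant-plume water,
#: six non-buoyant-plume experiments of which four consume H2 at zero-order
#: rates averaging 30 nM/d, CH4 stable everywhere.
DEFAULT_INCUBATION_DESIGN: list[dict] = [
    dict(experiment_id="ref-h2", water_type="reference", gas="h2", c0_nM=165.0,
         rate_nM_d=0.0, times_d=(0, 1, 2, 3, 5)),
    dict(experiment_id="ref-ch4", water_type="reference", gas="ch4", c0_nM=31.0,
         rate_nM_d=0.0, times_d=(0, 1, 2, 3, 5)),
    dict(experiment_id="buoyant-h2", water_type="buoyant_plume", gas="h2", c0_nM=323.0,
         rate_nM_d=0.0, times_d=(0, 1, 2, 3, 5)),
    dict(experiment_id="nbp-ch4", water_type="nonbuoyant_plume", gas="ch4", c0_nM=200.0,
         rate_nM_d=0.0, times_d=(0, 1, 2, 3, 5)),
    dict(experiment_id="nbp-h2-1", water_type="nonbuoyant_plume", gas="h2", c0_nM=150.0,
         rate_nM_d=64.0, times_d=(0, 1, 2)),
    dict(experiment_id="nbp-h2-2", water_type="nonbuoyant_plume", gas="h2", c0_nM=150.0,
         rate_nM_d=25.0, times_d=(0, 2, 5)),
    dict(experiment_id="nbp-h2-3", water_type="nonbuoyant_plume", gas="h2", c0_nM=120.0,
         rate_nM_d=18.0, times_d=(0, 2, 5)),
    dict(experiment_id="nbp-h2-4", water_type="nonbuoyant_plume", gas="h2", c0_nM=100.0,
         rate_nM_d=13.0, times_d=(0, 2, 5)),
    dict(experiment_id="nbp-h2-5", water_type="nonbuoyant_plume", gas="h2", c0_nM=150.0,
         rate_nM_d=0.0, times_d=(0, 1, 2, 3, 5)),
    dict(experiment_id="nbp-h2-6", water_type="nonbuoyant_plume", gas="h2", c0_nM=140.0,
         rate_nM_d=0.0, times_d=(0, 1, 2, 3, 5)),
]


def generate_incubations(
    scenario: VentScenario,
    design: Sequence[dict] | None = None,
    bottles_per_timepoint: int = 3,
) -> tuple[list[IncubationSeries], dict]:
    """Incubation time courses from a per-experiment truth design.

    Each design entry gives the water type, gas, initial concentration,
    and a zero-order consumption rate (``rate_nM_d``) or first-order
    constant (``k_per_d``). The forward model evolves the concentration,
    floors it at zero, applies proportional measurement noise, and
    reports the headspace mixing ratio from the complete-transfer model
    (so the conversion round-trips exactly in that mode).
    """
    if design is None:
        design = DEFAULT_INCUBATION_DESIGN
    rng = scenario.rng(_STREAM_INCUBATIONS)
    noise = scenario.noise
    series: list[IncubationSeries] = []
    truth_entries = []
    for entry in design:
        times = np.asarray(entry["times_d"], dtype=float)
        c0 = float(entry["c0_nM"])
        if "k_per_d" in entry:
            true_c = c0 * np.exp(-entry["k_per_d"] * times)
            model = "first_order"
        else:
            true_c = np.maximum(c0 - entry.get("rate_nM_d", 0.0) * times, 0.0)
            model = "zero_order"
        recs = []
        for j, t in enumerate(times):
            for b in range(bottles_per_timepoint):
                c_obs = max(0.0, true_c[j] * (1 + rng.normal(0, noise.concentration_cv)))
                recs.append(
                    {
                        "bottle_id": f"{entry['experiment_id']}-t{j}-b{b}",
                        "time_d": t,
                        "ppmv": dissolved_to_headspace(c_obs),
                    }
                )
        series.append(
            IncubationSeries(
                experiment_id=entry["experiment_id"],
                water_type=entry["water_type"],
                gas=entry["gas"],
                data=pd.DataFrame(recs),
            )
        )
        truth_entries.append({**entry, "times_d": list(map(float, times)), "model": model})
    consuming = [e.get("rate_nM_d", 0.0) for e in design if e.get("rate_nM_d", 0.0) > 0]
    truth = {
        "experiments": truth_entries,
        "n_consuming": len(consuming),
        "n_total": len(design),
        "mean_consuming_rate_nM_d": float(np.mean(consuming)) if consuming else None,
        "seed": scenario.seed,
    }
    return series, truth


def generate_dcf_assays(
    scenario: VentScenario,
    true_rates_umol_m3_d: Sequence[float] | None = None,
    water_types: Sequence[str] | None = None,
    time_d: float = 0.5,
    blank_dpm: float = 50.0,
    n_killed: int = 2,
) -> tuple[list[DcfAssay], dict]:
    """14C-bicarbonate fixation assays at known true rates.

    Default campaign: plume rates drawn uniform on [5, 45] and
    background rates on [0.5, 1] umol C m-3 d-1 (8 samples each).
    Counts are Poisson when the scenario's noise model says so.
    """
    rng = scenario.rng(_STREAM_ASSAYS)
    if true_rates_umol_m3_d is None:
        plume = rng.uniform(5.0, 45.0, 8)
        background = rng.uniform(0.5, 1.0, 8)
        true_rates_umol_m3_d = np.concatenate([plume, background])
        water_types = ["plume"] * 8 + ["reference"] * 8
    rates = np.asarray(true_rates_umol_m3_d, dtype=float)
    if water_types is None:
        water_types = ["plume"] * rates.size
    added_dpm = 1380.0 * 1000.0 * DPM_PER_BQ
    assays: list[DcfAssay] = []
    for i, (rate, wt) in enumerate(zip(rates, water_types)):
        t = time_d if wt == "plume" else 2.0
        frac = rate * t / (2100.0 * ISOTOPE_DISCRIMINATION * 1000.0)
        expected_net = frac * added_dpm
        if scenario.noise.counting:
            killed = rng.poisson(blank_dpm, n_killed).astype(float)
            sample = float(rng.poisson(blank_dpm + expected_net))
        else:
            killed = np.full(n_killed, blank_dpm)
            sample = blank_dpm + expected_net
        assays.append(
            DcfAssay(
                sample_id=f"{scenario.name}-dcf-{i:03d}",
                dpm_sample=sample,
                dpm_blank=float(killed.mean()),
                blank_sd=float(killed.std(ddof=1)) if n_killed > 1 else 0.0,
                time_d=t,
            )
        )
    truth = {
        "true_rates_umol_m3_d": rates.tolist(),
        "water_types": list(water_types),
        "blank_dpm": blank_dpm,
        "seed": scenario.seed,
    }
    return assays, truth


def generate_mox_assays(
    scenario: VentScenario,
    true_f_ox: Sequence[float] | None = None,
    ch4_nM: float = 30.0,
    time_d: float = 3.0,
    blank_dpm: float = 40.0,
    n_killed: int = 3,
) -> tuple[list[MoxAssay], dict]:
    """14C-CH4 oxidation assays at known true oxidized fractions."""
    rng = scenario.rng(_STREAM_ASSAYS + 10)
    if true_f_ox is None:
        true_f_ox = [0.0] * 6 + [1e-3] * 2
    added_dpm = 1.0 * 1000.0 * DPM_PER_BQ
    assays: list[MoxAssay] = []
    for i, f in enumerate(true_f_ox):
        if scenario.noise.counting:
            killed = rng.poisson(blank_dpm, n_killed).astype(float)
            sample = float(rng.poisson(blank_dpm + f * added_dpm))
        else:
            killed = np.full(n_killed, blank_dpm)
            sample = blank_dpm + f * added_dpm
        assays.append(
            MoxAssay(
                sample_id=f"{scenario.name}-mox-{i:03d}",
                ch4_nM=ch4_nM,
                dpm_14c_ic=sample,
                killed_control_dpms=killed.tolist(),
                dpm_14ch4_added=added_dpm,
                time_d=time_d,
            )
        )
    truth = {
        "true_f_ox": list(map(float, true_f_ox)),
        "ch4_nM": ch4_nM,
        "time_d": time_d,
        "blank_dpm": blank_dpm,
        "seed": scenario.seed,
    }
    return assays, truth


def write_bundle(scenario: VentScenario, out_dir: str | Path) -> dict:
    """Write the full synthetic campaign to disk; returns the combined ledger.

    Layout: casts/<id>.csv, bottles.csv, incubations.csv, dcf_assays.csv,
    mox_assays.csv, ledger.json. The ledger records the scenario, the
    seed, and every generator's ground truth.
    """
    out = Path(out_dir)
    (out / "casts").mkdir(parents=True, exist_ok=True)
    refs, plumes, cast_truth = generate_casts(scenario)
    for cast in refs + plumes:
        cast.data.to_csv(out / "casts" / f"{cast.cast_id}.csv", index=False)
    bottles, bottle_truth = generate_bottles(scenario)
    bottles.to_csv(out / "bottles.csv", index=False)

    series, inc_truth = generate_incubations(scenario)
    inc_rows = []
    for s in series:
        df = s.data.copy()
        df.insert(0, "experiment_id", s.experiment_id)
        df.insert(1, "water_type", s.water_type)
        df.insert(2, "gas", s.gas)
        inc_rows.append(df)
    pd.concat(inc_rows, ignore_index=True).to_csv(out / "incubations.csv", index=False)

    dcf, dcf_truth = generate_dcf_assays(scenario)
    dcf_rows = []
    for a in dcf:
        dcf_rows.append({"sample_id": a.sample_id, "role": "live", "dpm": a.dpm_sample, "time_d": a.time_d})
        dcf_rows.append({"sample_id": a.sample_id, "role": "killed", "dpm": a.dpm_blank, "time_d": a.time_d})
    pd.DataFrame(dcf_rows).to_csv(out / "dcf_assays.csv", index=False)

    mox, mox_truth = generate_mox_assays(scenario)
    mox_rows = []
    for a in mox:
        mox_rows.append({"sample_id": a.sample_id, "role": "live", "dpm": a.dpm_14c_ic,
                         "ch4_nM": a.ch4_nM, "time_d": a.time_d, "dpm_14ch4_added": a.dpm_14ch4_added})
        for kd in a.killed_control_dpms:
            mox_rows.append({"sample_id": a.sample_id, "role": "killed", "dpm": kd,
                             "ch4_nM": a.ch4_nM, "time_d": a.time_d, "dpm_14ch4_added": a.dpm_14ch4_added})
    pd.DataFrame(mox_rows).to_csv(out / "mox_assays.csv", index=False)

    ledger = {
        "scenario": scenario.describe(),
        "casts": cast_truth,
        "bottles": bottle_truth,
        "incubations": inc_truth,
        "dcf_assays": dcf_truth,
        "mox_assays": mox_truth,
    }
    with open(out / "ledger.json", "w") as fh:
        json.dump(ledger, fh, indent=2, sort_keys=True)
    return ledger
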