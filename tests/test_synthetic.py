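"""Synthetic-data generator: determinism, ledgers, forward-model consistency."""

import json

import numpy as np
import pandas as pd
import pytest

from ventplume import synthetic as syn
from ventplume.incubation import headspace_to_dissolved
from ventplume.endmember import validate_bottles


class TestScenario:
    def test_presets_carry_published_style_endmembers(self):
        p = syn.preset("polaris")
        a = syn.preset("aurora")
        assert p.composition_mM["ch4"] == 2.7 and p.composition_mM["h2"] == 3.3
        assert a.composition_mM == {"ch4": 1.4, "h2": 14.0, "fe": 6.8, "mn": 0.7}
        assert p.endmember_T_C == 270 and a.endmember_T_C == 370

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            syn.preset("loki")

    def test_invalid_scenario_rejected(self):
        with pytest.raises(ValueError):
            syn.preset("polaris", endmember_T_C=500.0)


class TestDeterminism:
    def test_identical_seed_identical_bottles(self):
        a, _ = syn.generate_bottles(syn.preset("polaris", seed=9))
        b, _ = syn.generate_bottles(syn.preset("polaris", seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_different_draws(self):
        a, _ = syn.generate_bottles(syn.preset("polaris", seed=1))
        b, _ = syn.generate_bottles(syn.preset("polaris", seed=2))
        assert not a["ch4_nM"].equals(b["ch4_nM"])

    def test_substreams_keep_tables_independent(self):
        # enlarging the cast table must not perturb the bottle table
        sc = syn.preset("polaris", seed=4)
        bottles_before, _ = syn.generate_bottles(sc)
        syn.generate_casts(sc, n_reference=5, n_plume=4)
        bottles_after, _ = syn.generate_bottles(sc)
        pd.testing.assert_frame_equal(bottles_before, bottles_after)


class TestCasts:
    def test_noise_free_anomaly_equals_injected_shape(self):
        sc = syn.preset(
            "polaris",
            noise=syn.NoiseModel(
                ctd_temperature_mK=0, turbidity_NTU=0, eh_mV=0, sigma_density=0
            ),
        )
        refs, plumes, truth = syn.generate_casts(sc)
        ref = refs[0].data
        pl = plumes[0].data
        diff = pl["turbidity_NTU"] - ref["turbidity_NTU"]
        inside = (pl["depth_m"] >= truth["plume_top_m"]) & (
            pl["depth_m"] <= truth["plume_bottom_m"]
        )
        assert np.allclose(diff[inside], truth["turbidity_anomaly_NTU"])
        outside = pl["depth_m"] < truth["plume_top_m"] - 20
        assert np.allclose(diff[outside], 0.0)

    def test_ledger_matches_scenario(self, polaris, polaris_casts):
        _, _, truth = polaris_casts
        assert truth["N_per_s"] == polaris.N_per_s
        assert truth["seed"] == polaris.seed


class TestBottles:
    def test_table_satisfies_schema_invariants(self, polaris_bottles):
        table, _ = polaris_bottles
        validate_bottles(table)
        assert set(table["water_type"]) == {"plume", "reference"}
        assert (table["delta_T_mK"] >= 0).all()

    def test_dilutions_respect_truncation(self, polaris, polaris_bottles):
        _, truth = polaris_bottles
        assert min(truth["dilutions"]) >= polaris.min_dilution

    def test_conservative_ratio_constant_without_consumption_or_noise(self):
        sc = syn.preset(
            "polaris",
            h2_consumption_k_per_d=0.0,
            background_nM={"ch4": 0.0, "h2": 0.0, "fe": 0.0, "mn": 0.0},
            noise=syn.NoiseModel(concentration_cv=0.0, delta_T_mK=0.0, d3He_percent=0.0),
        )
        table, truth = syn.generate_bottles(sc)
        plume = table[table.water_type == "plume"]
        ratio = plume["h2_nM"] / plume["ch4_nM"]
        em = truth["endmember_mM"]
        assert np.allclose(ratio, em["h2"] / em["ch4"], rtol=1e-9)

    def test_age_grows_with_dilution(self, polaris_bottles):
        _, truth = polaris_bottles
        d = np.array(truth["dilutions"])
        ages = np.array(truth["ages_d"])
        order = np.argsort(d)
        # jitter aside, the age trend follows the dilution trend
        assert np.corrcoef(np.log(d), ages)[0, 1] > 0.8
        assert ages[order[0]] < ages[order[-1]]


class TestIncubationsForwardModel:
    def test_first_order_truth_reaches_printed_depletion(self):
        sc = syn.preset("polaris", noise=syn.NoiseModel(concentration_cv=0.0))
        design = [
            dict(experiment_id="fast", water_type="nonbuoyant_plume", gas="h2",
                 c0_nM=150.0, k_per_d=0.96, times_d=(0, 2))
        ]
        series, truth = syn.generate_incubations(sc, design=design)
        conc = series[0].concentrations_nM()
        day2 = conc[conc.time_d == 2]["nM"]
        assert day2.mean() == pytest.approx(150 * np.exp(-0.96 * 2), rel=1e-9)
        assert day2.mean() == pytest.approx(22.0, rel=0.02)

    def test_headspace_round_trip_exact_in_complete_mode(self, polaris):
        series, _ = syn.generate_incubations(polaris)
        s = series[0]
        nM = s.concentrations_nM(mode="complete")["nM"]
        # invert the emitted ppmv independently
        manual = s.data["ppmv"].apply(lambda p: headspace_to_dissolved(p))
        assert np.allclose(sorted(nM), sorted(manual), rtol=1e-12)


class TestAssays:
    def test_zero_rate_assays_center_on_zero(self):
        sc = syn.preset("polaris", seed=21)
        from ventplume.radiotracer import dcf_rate

        assays, _ = syn.generate_dcf_assays(
            sc, true_rates_umol_m3_d=[0.0] * 400, water_types=["plume"] * 400
        )
        net = np.array([a.dpm_sample - a.dpm_blank for a in assays])
        assert abs(net.mean()) < 3 * net.std(ddof=1) / np.sqrt(net.size)

    def test_plume_and_background_rate_ranges_separate(self, polaris):
        from ventplume.radiotracer import dcf_rate

        assays, truth = syn.generate_dcf_assays(polaris)
        rates = {
            wt: [
                dcf_rate(a).rate_umol_m3_d
                for a, w in zip(assays, truth["water_types"])
                if w == wt
            ]
            for wt in ("plume", "reference")
        }
        assert min(rates["plume"]) > max(rates["reference"])


def test_write_bundle_layout_and_ledger(tmp_path, polaris):
    ledger = syn.write_bundle(polaris, tmp_path)
    for name in ("bottles.csv", "incubations.csv", "dcf_assays.csv", "mox_assays.csv", "ledger.json"):
        assert (tmp_path / name).exists()
    assert any((tmp_path / "casts").glob("*.csv"))
    on_disk = json.loads((tmp_path / "ledger.json").read_text())
    assert on_disk["scenario"]["seed"] == polaris.seed
    assert on_disk["bottles"]["endmember_mM"] == ledger["bottles"]["endmember_mM"]
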