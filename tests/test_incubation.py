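"""Headspace conversion and bottle-incubation consumption kinetics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ventplume.incubation import (
    IncubationSeries,
    dissolved_to_headspace,
    experiment_summary,
    fit_consumption,
    headspace_to_dissolved,
    read_incubations_csv,
)
from ventplume import synthetic as syn


def series_from_points(points, water_type="nonbuoyant_plume", gas="h2", **kwargs):
    rows = [
        {"bottle_id": f"b{i}", "time_d": t, "nM": c} for i, (t, c) in enumerate(points)
    ]
    return IncubationSeries(
        experiment_id="exp", water_type=water_type, gas=gas,
        data=pd.DataFrame(rows), **kwargs,
    )


class TestHeadspaceConversion:
    def test_hand_arithmetic(self):
        # 10 ppmv of a 1 mmol headspace into 231.9 mL of water
        assert headspace_to_dissolved(10.0) == pytest.approx(10e-9 / 0.2319 * 1e9, rel=1e-9)
        assert headspace_to_dissolved(10.0) == pytest.approx(43.1, rel=0.001)

    def test_zero_is_zero(self):
        assert headspace_to_dissolved(0.0) == 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(p=st.floats(min_value=0, max_value=1e4), c=st.floats(min_value=0.1, max_value=10))
    def test_linear_in_mixing_ratio(self, p, c):
        assert headspace_to_dissolved(c * p) == pytest.approx(
            c * headspace_to_dissolved(p), rel=1e-9, abs=1e-12
        )

    def test_round_trip_with_forward_model_exact(self):
        for nM in (0.0, 22.0, 150.0, 323.0):
            ppmv = dissolved_to_headspace(nM)
            assert headspace_to_dissolved(ppmv) == pytest.approx(nM, rel=1e-12, abs=1e-12)

    def test_henry_mode_credits_residual_dissolved_fraction(self):
        # equilibrium partition: total = headspace * (1 + Hcc * Vw/Vh)
        factor = 1 + 0.019 * 231.9 / 24.1
        assert headspace_to_dissolved(10.0, mode="henry", gas="h2") == pytest.approx(
            headspace_to_dissolved(10.0) * factor, rel=1e-9
        )

    def test_unknown_gas_in_henry_mode_rejected(self):
        with pytest.raises(ValueError):
            headspace_to_dissolved(10.0, mode="henry", gas="xenon")


class TestFitConsumption:
    def test_two_point_depletion_rates(self):
        # 150 nM to 22 nM in 2 days
        s = series_from_points([(0.0, 150.0), (2.0, 22.0)])
        zero = fit_consumption(s, model="zero_order")
        first = fit_consumption(s, model="first_order")
        assert zero.rate == pytest.approx(64.0, rel=1e-9)
        assert first.rate == pytest.approx(np.log(150 / 22) / 2, rel=1e-9)
        assert first.rate == pytest.approx(0.96, rel=0.01)

    def test_stable_reference_water(self):
        # 165 +/- 8 nM flat over 5 days
        rng = np.random.default_rng(2)
        pts = [(t, 165 + rng.normal(0, 8)) for t in (0, 1, 2, 3, 5) for _ in range(3)]
        est = fit_consumption(series_from_points(pts, water_type="reference"))
        assert est.verdict == "stable"

    def test_first_order_recovery_within_2_se(self):
        rng = np.random.default_rng(7)
        k = 0.5
        pts = [
            (t, 150 * np.exp(-k * t) * (1 + rng.normal(0, 0.10)))
            for t in (0, 1, 2, 3, 5)
            for _ in range(3)
        ]
        est = fit_consumption(series_from_points(pts), model="first_order")
        assert est.verdict == "consumed"
        assert abs(est.rate - k) < 2 * est.se

    def test_models_agree_in_small_depletion_limit(self):
        # <=10% depletion: zero-order rate ~ k * C0
        k, c0 = 0.02, 200.0
        pts = [(t, c0 * np.exp(-k * t)) for t in np.linspace(0, 5, 6)]
        zero = fit_consumption(series_from_points(pts), model="zero_order")
        first = fit_consumption(series_from_points(pts), model="first_order")
        assert zero.rate == pytest.approx(first.rate * first.c0, rel=0.06)

    def test_all_zero_concentrations_rejected_for_first_order(self):
        s = series_from_points([(0.0, 0.0), (1.0, 0.0), (2.0, 0.0)])
        with pytest.raises(ValueError):
            fit_consumption(s, model="first_order")

    def test_single_time_point_rejected(self):
        s = series_from_points([(1.0, 10.0), (1.0, 12.0)])
        with pytest.raises(ValueError):
            fit_consumption(s)

    def test_type_i_control_on_flat_series(self):
        # flat truth: "consumed" must fire in <= alpha of seeded replicates
        false_pos = 0
        n_rep = 400
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            pts = [
                (t, 150 * (1 + rng.normal(0, 0.05)))
                for t in (0, 1, 2, 3, 5)
                for _ in range(3)
            ]
            est = fit_consumption(series_from_points(pts))
            false_pos += est.verdict == "consumed"
        assert false_pos / n_rep <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)


class TestSummary:
    def test_all_stable(self):
        ests = [
            fit_consumption(series_from_points([(0, 100.0), (1, 100.0), (2, 100.0)]))
        ]
        s = experiment_summary(ests)
        assert s["n_consumed"] == 0
        assert s["mean_consumption_rate_umol_m3_d"] is None

    def test_default_campaign_four_of_six_consuming_at_30(self, polaris):
        series, truth = syn.generate_incubations(polaris)
        ests = [fit_consumption(s) for s in series]
        summary = experiment_summary(ests)
        nbp_h2 = summary["counts_by_water_type"]["nonbuoyant_plume"]
        assert summary["n_consumed"] == truth["n_consuming"] == 4
        assert nbp_h2["consumed"] == 4
        assert summary["counts_by_water_type"]["reference"]["consumed"] == 0
        assert summary["mean_consumption_rate_umol_m3_d"] == pytest.approx(
            truth["mean_consuming_rate_nM_d"], rel=0.15
        )
        assert truth["mean_consuming_rate_nM_d"] == 30.0


def test_csv_reader_groups_experiments(tmp_path, polaris):
    series, _ = syn.generate_incubations(polaris)
    rows = []
    for s in series:
        df = s.data.copy()
        df.insert(0, "experiment_id", s.experiment_id)
        df.insert(1, "water_type", s.water_type)
        df.insert(2, "gas", s.gas)
        rows.append(df)
    path = tmp_path / "inc.csv"
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    back = read_incubations_csv(path)
    assert len(back) == len(series)
    a = fit_consumption(series[0])
    b = fit_consumption(back[0])
    assert a.rate == pytest.approx(b.rate, rel=1e-9)
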