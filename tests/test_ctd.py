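"""Water-column module: backgrounds, anomalies, plume delineation, stratification."""

import numpy as np
import pandas as pd
import pytest

from ventplume import ctd as ctd_mod
from ventplume.ctd import (
    CtdCast,
    DepthRangeError,
    PropertyMissingError,
    anomaly,
    buoyancy_frequency,
    delineate_plume,
    fit_background,
)
from ventplume.seawater import density_at_surface

from conftest import make_cast


class TestBackground:
    def test_constant_profile_reproduced_with_zero_sd(self):
        depths = np.arange(2000, 3000, 100.0)
        cast = make_cast(depths, turbidity_NTU=np.full(depths.size, 0.1))
        bg = fit_background([cast], "turbidity_NTU")
        q = np.linspace(2000, 2900, 7)
        assert np.allclose(bg.value(q), 0.1)
        assert np.allclose(bg.sd(q), 0.0)

    def test_two_cast_median_and_cross_cast_sd(self):
        depths = np.arange(2000, 3000, 100.0)
        a = make_cast(depths, cast_id="a", turbidity_NTU=np.full(depths.size, 0.1))
        b = make_cast(depths, cast_id="b", turbidity_NTU=np.full(depths.size, 0.3))
        bg = fit_background([a, b], "turbidity_NTU")
        assert np.allclose(bg.value(2500.0), 0.2)
        # n-1 SD of {0.1, 0.3}
        assert np.allclose(bg.sd(2500.0), np.sqrt(0.02), atol=1e-12)

    def test_missing_property_raises(self):
        cast = make_cast(np.arange(100, 700, 100.0))
        with pytest.raises(PropertyMissingError):
            fit_background([cast], "turbidity_NTU")

    def test_out_of_range_query_raises(self):
        depths = np.arange(2000, 3000, 100.0)
        cast = make_cast(depths, turbidity_NTU=np.full(depths.size, 0.1))
        bg = fit_background([cast], "turbidity_NTU")
        with pytest.raises(DepthRangeError):
            bg.value(500.0)

    def test_noisy_references_recover_truth(self, polaris, polaris_casts):
        refs, _, truth = polaris_casts
        bg = fit_background(refs, "turbidity_NTU")
        sigma = truth["noise"]["turbidity_NTU"]
        n = len(refs)
        grid = bg.depth_grid[1:-1]
        assert np.all(
            np.abs(bg.values[1:-1] - truth["turbidity_background_NTU"]) < 3 * sigma / np.sqrt(n)
        ), f"background off at some of {grid.size} nodes"


class TestAnomaly:
    def test_cast_as_own_reference_gives_zero_anomaly(self):
        rng = np.random.default_rng(0)
        depths = np.arange(2000, 3000, 50.0)
        cast = make_cast(depths, turbidity_NTU=0.1 + rng.normal(0, 0.02, depths.size))
        bg = fit_background([cast], "turbidity_NTU", bin_width_m=25.0)
        an = anomaly(cast, bg, "turbidity_NTU")
        # every observation sits exactly on its own single-cast background node
        assert np.allclose(an["anomaly"], 0.0, atol=1e-12)

    def test_sign_preserved_for_redox(self):
        depths = np.arange(2500.0, 2900.0, 50.0)
        ref = make_cast(depths, eh_offset_mV=np.zeros(depths.size))
        obs = make_cast(depths, eh_offset_mV=np.full(depths.size, -25.0))
        bg = fit_background([ref], "eh_offset_mV")
        an = anomaly(obs, bg, "eh_offset_mV")
        assert np.allclose(an["anomaly"], -25.0)

    def test_no_depth_overlap_raises(self):
        ref = make_cast(np.arange(2000, 2500, 50.0), turbidity_NTU=np.full(10, 0.1))
        far = make_cast(np.arange(3000, 3500, 50.0), turbidity_NTU=np.full(10, 0.1))
        bg = fit_background([ref], "turbidity_NTU")
        with pytest.raises(DepthRangeError):
            anomaly(far, bg, "turbidity_NTU")


class TestDelineation:
    @staticmethod
    def series(depths, values, sd=0.01):
        return pd.DataFrame(
            {"depth_m": depths, "anomaly": values, "residual_sd": np.full(len(depths), sd)}
        )

    def test_all_below_threshold_returns_none(self):
        s = self.series(np.arange(2000, 3000, 50.0), np.zeros(20))
        assert delineate_plume(s, "turbidity_NTU") is None

    def test_longest_of_two_blocks_wins(self):
        depths = np.arange(2000, 3000, 50.0)
        vals = np.zeros(depths.size)
        vals[(depths >= 2100) & (depths <= 2200)] = 1.0  # 100 m block
        vals[(depths >= 2500) & (depths <= 2800)] = 1.0  # 300 m block
        iv = delineate_plume(self.series(depths, vals), "x", threshold=0.5)
        assert iv.top_depth_m == 2500 and iv.bottom_depth_m == 2800

    def test_equal_blocks_tie_break_deepest(self):
        depths = np.arange(2000, 3000, 50.0)
        vals = np.zeros(depths.size)
        vals[(depths >= 2100) & (depths <= 2200)] = 1.0
        vals[(depths >= 2600) & (depths <= 2700)] = 1.0
        iv = delineate_plume(self.series(depths, vals), "x", threshold=0.5)
        assert iv.top_depth_m == 2600

    def test_record_order_invariance(self):
        rng = np.random.default_rng(1)
        depths = np.arange(2000, 3000, 50.0)
        vals = np.where((depths > 2400) & (depths < 2700), 1.0, 0.0)
        s = self.series(depths, vals)
        shuffled = s.sample(frac=1, random_state=2).reset_index(drop=True)
        a = delineate_plume(s, "x", threshold=0.5)
        b = delineate_plume(shuffled, "x", threshold=0.5)
        assert a == b

    def test_negative_anomaly_block_delineated(self):
        depths = np.arange(2000, 3000, 50.0)
        vals = np.where((depths >= 2400) & (depths <= 2800), -25.0, 0.0)
        iv = delineate_plume(self.series(depths, vals), "eh", threshold=10.0)
        assert iv.peak_anomaly < 0
        assert (iv.top_depth_m, iv.bottom_depth_m) == (2400, 2800)

    def test_synthetic_plume_interval_recovered(self, polaris, polaris_casts):
        refs, plumes, truth = polaris_casts
        bg = fit_background(refs, "turbidity_NTU")
        iv = delineate_plume(anomaly(plumes[0], bg, "turbidity_NTU"), "turbidity_NTU")
        tol = 20.0 + truth["depth_grid_step_m"]  # ramp width + one grid step
        assert abs(iv.top_depth_m - truth["plume_top_m"]) <= tol
        assert abs(iv.bottom_depth_m - truth["plume_bottom_m"]) <= tol
        assert truth["plume_top_m"] <= iv.peak_depth_m <= truth["plume_bottom_m"]


class TestBuoyancyFrequency:
    def test_uniform_density_gives_zero(self):
        depths = np.arange(2000, 2500, 50.0)
        cast = make_cast(depths, sigma=np.full(depths.size, 27.8))
        assert buoyancy_frequency(cast, (2000, 2500)) == 0.0

    def test_hand_computed_gradient(self):
        # 0.01 kg m-3 over 1000 m, rho0=1028: N = sqrt(9.81e-5/1028)
        depths = np.linspace(2000, 3000, 11)
        sigma = 27.8 + 0.01 * (depths - 2000) / 1000
        cast = make_cast(depths, sigma=sigma)
        n = buoyancy_frequency(cast, (2000, 3000))
        assert n == pytest.approx(np.sqrt(9.81 * 1e-5 / 1028), rel=1e-9)
        assert n == pytest.approx(3.09e-4, rel=0.01)

    def test_constant_density_offset_invariance(self):
        depths = np.linspace(2000, 3000, 21)
        sigma = 27.8 + 1e-5 * (depths - 2000)
        a = buoyancy_frequency(make_cast(depths, sigma=sigma), (2000, 3000))
        b = buoyancy_frequency(make_cast(depths, sigma=sigma + 0.5), (2000, 3000))
        assert a == pytest.approx(b, rel=1e-12)

    def test_unstable_window_warns_and_returns_zero(self):
        depths = np.linspace(2000, 3000, 11)
        cast = make_cast(depths, sigma=28.0 - 0.01 * (depths - 2000) / 1000)
        with pytest.warns(UserWarning):
            assert buoyancy_frequency(cast, (2000, 3000)) == 0.0

    def test_synthetic_stratification_recovered_within_2pct(self, polaris, polaris_casts):
        refs, _, truth = polaris_casts
        lo = truth["plume_top_m"] - 300
        hi = truth["plume_bottom_m"] + 200
        n = buoyancy_frequency(refs[0], (lo, hi))
        assert n == pytest.approx(truth["N_per_s"], rel=0.02)

    def test_density_derived_from_t_s_when_sigma_missing(self):
        depths = np.linspace(2000, 3000, 11)
        t = np.linspace(0.0, -0.8, 11)
        cast = make_cast(depths, temperature_C=t, salinity=np.full(11, 34.9))
        n = buoyancy_frequency(cast, (2000, 3000))
        assert n > 0  # cooling with depth stabilizes the column


def test_seawater_density_matches_published_check_value():
    # standard one-atmosphere check point of the EOS-80 polynomial
    assert density_at_surface(35.0, 25.0) == pytest.approx(1023.34306, abs=1e-4)
    assert density_at_surface(0.0, 5.0) == pytest.approx(999.96675, abs=1e-4)


def test_cast_validation():
    with pytest.raises(ValueError):
        make_cast([-10.0, 100.0])
    with pytest.raises(ValueError):
        make_cast([10.0, 100.0], temperature_C=[50.0, 0.0])


def test_cast_csv_round_trip(tmp_path):
    depths = np.arange(2000, 2500, 100.0)
    cast = make_cast(depths, cast_id="ps-1", turbidity_NTU=np.full(5, 0.1))
    p = tmp_path / "ps-1.csv"
    cast.data.to_csv(p, index=False)
    back = ctd_mod.read_cast_csv(p)
    assert back.cast_id == "ps-1"
    pd.testing.assert_frame_equal(
        back.data[["depth_m", "turbidity_NTU"]], cast.data[["depth_m", "turbidity_NTU"]]
    )
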