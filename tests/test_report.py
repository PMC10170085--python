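"""Tests of zonal summaries, regressions, rasters and densities."""

import numpy as np
import pandas as pd
import pytest

from socbackcast import report


class TestSampleFraction:
    def test_identity(self):
        t = pd.DataFrame({"x": range(10)})
        out = report.sample_fraction(t, 1.0, seed=0)
        pd.testing.assert_frame_equal(out, t)

    def test_exact_count_round_half_up(self):
        t = pd.DataFrame({"x": range(10000)})
        assert len(report.sample_fraction(t, 0.01, seed=0)) == 100
        assert len(report.sample_fraction(pd.DataFrame({"x": range(50)}), 0.01, 1)) == 1

    def test_reproducible(self):
        t = pd.DataFrame({"x": range(1000)})
        a = report.sample_fraction(t, 0.1, seed=5)
        b = report.sample_fraction(t, 0.1, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            report.sample_fraction(pd.DataFrame({"x": [1]}), 0.0)


def results_frame(rows):
    base = dict.fromkeys(["delta_100", "delta_50", "rel_100", "rel_50"], 0.0)
    out = []
    for r in rows:
        d = dict(base)
        d.update(r)
        out.append(d)
    return pd.DataFrame(out)


class TestZoneSummary:
    def test_single_site_zone(self):
        res = results_frame([
            {"koppen_zone": "Af", "scenario": "NPP_const", "delta_100": -1.5},
        ])
        zs = report.zone_summary(res)
        assert len(zs) == 1
        assert zs.iloc[0]["delta_100_mean"] == -1.5
        assert zs.iloc[0]["delta_100_sd"] == 0.0
        assert zs.iloc[0]["n"] == 1

    def test_hand_arithmetic_mean_and_sample_sd(self):
        res = results_frame([
            {"koppen_zone": "Af", "scenario": "NPP_const", "delta_100": -1.0},
            {"koppen_zone": "Af", "scenario": "NPP_const", "delta_100": -3.0},
        ])
        zs = report.zone_summary(res)
        assert zs.iloc[0]["delta_100_mean"] == pytest.approx(-2.0)
        assert zs.iloc[0]["delta_100_sd"] == pytest.approx(np.sqrt(2.0))

    def test_pooled_mean_identity(self, small_world_results):
        zs = report.zone_summary(small_world_results)
        const = zs[zs.scenario == "NPP_const"]
        pooled = (const["delta_100_mean"] * const["n"]).sum() / const["n"].sum()
        direct = small_world_results[
            small_world_results.scenario == "NPP_const"]["delta_100"].mean()
        assert pooled == pytest.approx(direct, rel=1e-12)

    def test_permutation_invariance(self, small_world_results):
        shuffled = small_world_results.sample(frac=1.0, random_state=1)
        a = report.zone_summary(small_world_results)
        b = report.zone_summary(shuffled)
        pd.testing.assert_frame_equal(a, b)


def driver_table(n=27, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "soc_2018": rng.uniform(10, 120, n),
        "mat_mean": rng.uniform(-5, 25, n),
        "map_mean": rng.uniform(200, 2000, n),
        "water_balance": rng.uniform(-500, 800, n),
        "d_mat": rng.uniform(0.3, 2.0, n),
        "d_map": rng.uniform(-80, 80, n),
        "d_water_balance": rng.uniform(-100, 100, n),
    })


class TestRegressionSelect:
    def test_noise_response_beats_full_model(self):
        t = driver_table(seed=1)
        rng = np.random.default_rng(2)
        t["resp"] = rng.normal(0, 1, len(t))
        fit = report.regression_select(t, "resp")
        import statsmodels.api as sm

        full = sm.OLS(t["resp"],
                      sm.add_constant(t[report.DRIVER_COLUMNS])).fit()
        assert fit.aic <= full.aic

    def test_recovers_planted_coefficient_pattern(self):
        t = driver_table(seed=3)
        rng = np.random.default_rng(4)
        t["resp"] = (4.501 - 0.057 * t.soc_2018 - 4.318 * t.d_mat
                     - 0.019 * t.d_map + rng.normal(0, 0.3, len(t)))
        fit = report.regression_select(t, "resp")
        assert {"soc_2018", "d_mat", "d_map"} <= set(fit.predictors)
        assert fit.signs["soc_2018"] == -1
        assert fit.signs["d_mat"] == -1
        assert fit.signs["d_map"] == -1
        assert fit.coefficients["d_mat"] == pytest.approx(-4.318, rel=0.15)

    def test_single_predictor_truth(self):
        t = driver_table(seed=0)
        rng = np.random.default_rng(100)
        t["resp"] = 1.0 - 0.1 * t.soc_2018 + rng.normal(0, 0.2, len(t))
        fit = report.regression_select(t, "resp")
        assert fit.predictors == ("soc_2018",)

    def test_deterministic_search(self):
        t = driver_table(seed=7)
        t["resp"] = -0.05 * t.soc_2018 - 2.0 * t.d_mat
        a = report.regression_select(t, "resp")
        b = report.regression_select(t, "resp")
        assert a.predictors == b.predictors
        assert a.aic == b.aic

    def test_collinear_predictor_dropped(self):
        t = driver_table(seed=8)
        t["d_water_balance"] = 2.0 * t["d_map"]  # exact collinearity
        t["resp"] = -0.1 * t.soc_2018
        fit = report.regression_select(t, "resp")
        assert "d_water_balance" in fit.dropped_collinear


class TestRasterAggregate:
    def test_one_site_per_cell(self):
        res = pd.DataFrame({"lon": [0.01, 5.23], "lat": [0.04, -9.87],
                            "delta_100": [-1.0, 2.0]})
        grid = report.raster_aggregate(res)
        assert sorted(grid["mean"]) == [-1.0, 2.0]

    def test_two_sites_share_cell(self):
        res = pd.DataFrame({"lon": [0.01, 0.09], "lat": [0.02, 0.03],
                            "delta_100": [-1.0, -3.0]})
        grid = report.raster_aggregate(res)
        assert len(grid) == 1
        assert grid.iloc[0]["mean"] == -2.0

    def test_boundary_belongs_to_upper_cell(self):
        res = pd.DataFrame({"lon": [0.1], "lat": [0.0], "delta_100": [1.0]})
        grid = report.raster_aggregate(res)
        assert grid.iloc[0]["lon"] == pytest.approx(0.1)

    def test_out_of_domain_rejected(self):
        res = pd.DataFrame({"lon": [190.0], "lat": [0.0], "delta_100": [1.0]})
        with pytest.raises(ValueError):
            report.raster_aggregate(res)

    def test_tiff_written(self, tmp_path):
        import tifffile

        res = pd.DataFrame({"lon": [0.0, 0.1], "lat": [0.0, 0.0],
                            "delta_100": [1.0, 2.0]})
        grid = report.raster_aggregate(res)
        path = report.write_raster_tiff(grid, tmp_path / "g.tif")
        band = tifffile.imread(path)
        assert band.shape == (1, 2)
        assert sorted(band.ravel()) == [1.0, 2.0]


class TestChangeDensity:
    def test_single_bin_captures_all(self):
        d = report.change_density(np.full(10, -1.5), edges=np.array([-3.0, 0.0]))
        row = d[(d.lo == -3.0) & (d.hi == 0.0)].iloc[0]
        assert row.fraction == 1.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        d = report.change_density(rng.normal(0, 5, 500))
        assert d.fraction.sum() == pytest.approx(1.0)

    def test_hand_counted_fractions(self):
        vals = np.array([-4.0, -2.5, -2.0, -0.1, 0.0, 0.5, 1.0, 2.9, 3.0, 7.0])
        d = report.change_density(vals, edges=np.array([-3.0, 0.0, 3.0]))
        assert d[(d.lo == -3.0) & (d.hi == 0.0)].iloc[0].fraction == 0.4
        assert d[(d.lo == 0.0) & (d.hi == 3.0)].iloc[0].fraction == 0.4
        assert d[np.isinf(d.lo)].iloc[0].fraction == 0.1
        assert d[np.isinf(d.hi)].iloc[0].fraction == 0.1
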