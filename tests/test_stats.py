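"""Cross-year statistics: predictor aggregation against groupby oracles,
forest-importance recovery properties, OLS regression and the period
split."""

import numpy as np
import pandas as pd
import pytest

from monomict.simulate import SimOutput
from monomict.stats import (PREDICTORS, aggregate_predictors,
                            forest_importance, linear_fit, period_split_fit)


def _fake_simout(dates, temp_s, temp_b, do_s, do_b, dens_s, dens_b, poc_s):
    """Two-layer stand-in archive (synthetic) for aggregation tests."""
    nd = len(dates)
    zeros = np.zeros((nd, 2))

    def two(a, b):
        return np.column_stack([np.broadcast_to(a, nd),
                                np.broadcast_to(b, nd)])

    data = {"temp": two(temp_s, temp_b), "density": two(dens_s, dens_b),
            "do": two(do_s, do_b), "poc": two(poc_s, poc_s),
            "phy": zeros, "zoo": zeros, "din": zeros, "dip": zeros,
            "dic": zeros}
    empty = pd.DataFrame(index=dates)
    state = np.zeros((7, 2))
    return SimOutput(time=pd.DatetimeIndex(dates), depths=np.array([1.25, 3.75]),
                     data=data, sediment=empty, ledger=empty, meta={},
                     initial_temp=np.zeros(2), initial_tracers=state,
                     initial_sed=np.zeros(3), final_temp=np.zeros(2),
                     final_tracers=state, final_sed=np.zeros(3))


def _winter_mixing_series(dates, mix_dates):
    """Surface/bottom temp & DO that co-satisfy the criterion from each
    year's mixing date to the end of April."""
    t_s = np.full(len(dates), 9.0)
    do_b = np.full(len(dates), 5.0)
    for md in mix_dates:
        lo = pd.Timestamp(md)
        hi = pd.Timestamp(lo.year, 4, 30)
        sel = (dates >= lo) & (dates <= hi)
        t_s[sel] = 7.6
        do_b[sel] = 10.45
    return t_s, do_b


class TestAggregatePredictors:
    def test_constant_inputs_aggregate_to_the_constant(self):
        dates = pd.date_range("1999-01-01", "2001-12-31")
        meteo = pd.DataFrame({
            "date": dates, "air_temp_c": 6.0, "wind_ms": 3.5,
            "cloud_frac": 0.5, "precip_mm": 4.0, "shortwave_wm2": 120.0})
        t_s, do_b = _winter_mixing_series(dates, ["2000-02-10", "2001-02-20"])
        out = _fake_simout(dates, t_s, 7.5, 10.5, do_b,
                           dens_s=999.9, dens_b=999.9, poc_s=25.0)
        tab = aggregate_predictors(out, meteo, mode="cold_season")
        for year in (2000, 2001):
            assert tab.loc[year, "AT"] == pytest.approx(6.0)
            assert tab.loc[year, "WS"] == pytest.approx(3.5)
            assert tab.loc[year, "CC"] == pytest.approx(0.5)
            assert tab.loc[year, "POC"] == pytest.approx(25.0)
            # isothermal column -> zero density difference
            assert tab.loc[year, "DD"] == pytest.approx(0.0)
        assert tab.loc[2000, "timing"] == 40      # Feb 10
        assert tab.loc[2001, "timing"] == 50      # Feb 20

    def test_matches_independent_groupby_oracle(self, rng):
        dates = pd.date_range("1999-01-01", "2001-12-31")
        meteo = pd.DataFrame({
            "date": dates,
            "air_temp_c": rng.normal(10, 5, len(dates)),
            "wind_ms": rng.uniform(1, 6, len(dates)),
            "cloud_frac": rng.uniform(0, 1, len(dates)),
            "precip_mm": rng.uniform(0, 12, len(dates)),
            "shortwave_wm2": rng.uniform(30, 300, len(dates))})
        t_s, do_b = _winter_mixing_series(dates, ["2000-02-10", "2001-02-20"])
        out = _fake_simout(dates, t_s, 7.5, 10.5, do_b,
                           dens_s=999.7, dens_b=999.95, poc_s=25.0)
        tab = aggregate_predictors(out, meteo, mode="cold_season")
        m = meteo.set_index("date")
        for year in (2000, 2001):
            win = m.loc[f"{year - 1}-11-01":f"{year}-04-30"]
            assert tab.loc[year, "AT"] == pytest.approx(
                win["air_temp_c"].mean())
            assert tab.loc[year, "pptn"] == pytest.approx(
                win["precip_mm"].mean())
            assert tab.loc[year, "DD"] == pytest.approx(999.95 - 999.7)

    def test_annual_mode_uses_calendar_year(self, rng):
        dates = pd.date_range("1999-01-01", "2001-12-31")
        at = rng.normal(10, 5, len(dates))
        meteo = pd.DataFrame({
            "date": dates, "air_temp_c": at, "wind_ms": 3.0,
            "cloud_frac": 0.5, "precip_mm": 4.0, "shortwave_wm2": 120.0})
        t_s, do_b = _winter_mixing_series(dates, ["2000-02-10", "2001-02-20"])
        out = _fake_simout(dates, t_s, 7.5, 10.5, do_b, 999.9, 999.9, 20.0)
        tab = aggregate_predictors(out, meteo, mode="annual")
        sel = dates.year == 2000
        assert tab.loc[2000, "AT"] == pytest.approx(at[sel].mean())


def _planted_table(rng, n_years=30, noise=2.0):
    tab = pd.DataFrame({p: rng.normal(0, 1, n_years) for p in PREDICTORS})
    tab["timing"] = 45.0 - 20.0 * tab["WS"] + rng.normal(0, noise, n_years)
    tab["failed"] = False
    tab.index.name = "year"
    return tab


class TestForestImportance:
    def test_null_response_explains_nothing(self):
        hits = []
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            tab = pd.DataFrame({p: rng.normal(0, 1, 40) for p in PREDICTORS})
            tab["timing"] = rng.normal(50, 10, 40)
            tab["failed"] = False
            imp = forest_importance(tab, n_trees=300, seed=seed)
            hits.append(imp.var_explained)
        assert np.mean(hits) < 10.0

    def test_planted_driver_ranks_first_on_both_measures(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(2000 + seed)
            imp = forest_importance(_planted_table(rng), n_trees=300,
                                    seed=seed)
            if (imp.pct_inc_mse.idxmax() == "WS"
                    and imp.node_purity.idxmax() == "WS"):
                wins += 1
        assert wins >= 18

    def test_shuffling_a_predictor_never_raises_its_importance(self):
        for seed in range(5):
            rng = np.random.default_rng(3000 + seed)
            tab = _planted_table(rng)
            orig = forest_importance(tab, n_trees=300, seed=seed)
            shuf = tab.copy()
            shuf["WS"] = rng.permutation(shuf["WS"].to_numpy())
            broken = forest_importance(shuf, n_trees=300, seed=seed)
            assert broken.pct_inc_mse["WS"] < orig.pct_inc_mse["WS"]

    def test_seeded_determinism(self):
        rng = np.random.default_rng(7)
        tab = _planted_table(rng)
        a = forest_importance(tab, n_trees=100, seed=42)
        b = forest_importance(tab, n_trees=100, seed=42)
        pd.testing.assert_series_equal(a.pct_inc_mse, b.pct_inc_mse)
        assert a.var_explained == b.var_explained

    def test_variance_explained_bounded(self):
        rng = np.random.default_rng(8)
        imp = forest_importance(_planted_table(rng, noise=0.5), n_trees=300,
                                seed=0)
        assert imp.var_explained <= 100.0
        assert imp.var_explained > 50.0       # strong planted signal

    def test_too_few_rows_rejected(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError, match="8"):
            forest_importance(_planted_table(rng, n_years=5), seed=0)

    def test_failed_years_excluded_by_default(self):
        rng = np.random.default_rng(10)
        tab = _planted_table(rng)
        tab.loc[tab.index[:5], "failed"] = True
        tab.loc[tab.index[:5], "timing"] = np.nan
        imp = forest_importance(tab, n_trees=50, seed=0)
        assert imp.pct_inc_mse.notna().all()


class TestLinearFit:
    def test_exact_line_recovered(self):
        x = np.arange(10, dtype=float)
        fit = linear_fit(x, 2.0 * x + 1.0)
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_independent_data_have_near_zero_r2(self):
        rng = np.random.default_rng(11)
        fit = linear_fit(rng.normal(0, 1, 500), rng.normal(0, 1, 500))
        assert fit.r2 < 0.02

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            linear_fit(np.ones(5), np.arange(5.0))

    def test_ci_covers_planted_hypoxia_slope(self):
        # synthetic DIP–DO pairs: slope −0.841 mgDO per µgP, noise sized so
        # r² ≈ 0.67; the 95% CI must cover the true slope in ≥ 90/100 seeds
        true_slope, n = -0.841, 25
        covered, r2s = 0, []
        for seed in range(100):
            rng = np.random.default_rng(4000 + seed)
            dip = rng.normal(10.0, 3.0, n)
            sigma = abs(true_slope) * 3.0 * np.sqrt(1 / 0.67 - 1)
            do = 9.0 + true_slope * dip + rng.normal(0, sigma, n)
            fit = linear_fit(dip, do)
            r2s.append(fit.r2)
            if fit.ci_low <= true_slope <= fit.ci_high:
                covered += 1
        assert covered >= 90
        assert abs(np.mean(r2s) - 0.67) < 0.1


class TestPeriodSplit:
    def test_identical_data_give_equal_fits(self):
        x = np.tile(np.arange(6.0), 2)
        y = 3.0 * x - 1.0
        years = np.r_[np.arange(1975, 1981), np.arange(1981, 1987)]
        out = period_split_fit(x, y, years)
        assert out["before"].slope == pytest.approx(out["after"].slope)
        assert out["before"].n == out["after"].n == 6

    def test_piecewise_structure_detected(self):
        rng = np.random.default_rng(12)
        years = np.arange(1960, 2000)
        x = rng.uniform(5, 20, len(years))
        y = np.where(years <= 1980,
                     -0.8 * x + 10 + rng.normal(0, 0.3, len(years)),
                     rng.normal(4, 2, len(years)))
        out = period_split_fit(x, y, years)
        assert out["before"].r2 > out["after"].r2

    def test_equals_two_independent_fits(self):
        # decomposition oracle
        rng = np.random.default_rng(13)
        years = np.arange(1970, 1990)
        x = rng.uniform(0, 10, 20)
        y = rng.uniform(0, 10, 20)
        out = period_split_fit(x, y, years, split_year=1980)
        pre = years <= 1980
        assert out["before"] == linear_fit(x[pre], y[pre])
        assert out["after"] == linear_fit(x[~pre], y[~pre])

    def test_undersized_period_rejected(self):
        with pytest.raises(ValueError, match="need >= 3"):
            period_split_fit(np.arange(5.0), np.arange(5.0),
                             np.array([1978, 1979, 1980, 1981, 1982]))
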