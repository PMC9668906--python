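"""Turnover detection, curve-shape classification, validation metrics and
hypoxia indices, each against brute-force scans."""

import numpy as np
import pandas as pd
import pytest

from monomict.mixing import (TurnoverRecord, annual_hypoxia_index,
                             curve_shape, date_to_timing, detect_turnover,
                             observed_turnover_criterion, rmse_nrmse,
                             timing_to_date)


def _daily(year_start, year_end):
    return pd.date_range(f"{year_start}-10-01", f"{year_end}-05-31", freq="D")


def _frames(idx, t_s, t_b, do_s, do_b):
    surf = pd.DataFrame({"temp": t_s, "do": do_s}, index=idx)
    bot = pd.DataFrame({"temp": t_b, "do": do_b}, index=idx)
    return surf, bot


class TestDetectTurnover:
    def test_constructed_series_detects_feb_11(self):
        # both criteria first co-hold on Feb 11, 2008 -> 41 days past Jan 1
        idx = _daily(2007, 2008)
        target = pd.Timestamp("2008-02-11")
        before = idx < target
        t_s = np.where(before, 9.0, 7.8)
        t_b = np.full(len(idx), 7.6)
        do_s = np.full(len(idx), 10.5)
        do_b = np.where(before, 6.0, 10.45)
        rec = detect_turnover(*_frames(idx, t_s, t_b, do_s, do_b), 2008)
        assert not rec.failed
        assert rec.timing == 41
        assert rec.date == target
        assert rec.delta_t < 0.5 and rec.delta_do < 0.1

    def test_permanently_stratified_year_fails(self):
        idx = _daily(2008, 2009)
        rec = detect_turnover(*_frames(idx, 9.0, 7.5, 11.0, 5.0), 2009)
        assert rec.failed and rec.timing is None

    def test_december_detection_has_negative_timing(self):
        idx = _daily(2010, 2011)
        target = pd.Timestamp("2010-12-20")
        mixed = idx >= target
        t_s = np.where(mixed, 8.0, 12.0)
        rec = detect_turnover(*_frames(idx, t_s, 8.0, 10.5, 10.5), 2011)
        assert rec.timing == -12
        assert rec.date == target

    def test_random_series_match_brute_force_scan(self, rng):
        for _ in range(100):
            idx = _daily(2001, 2002)
            t_s = rng.uniform(6, 12, len(idx))
            t_b = rng.uniform(6, 12, len(idx))
            do_s = rng.uniform(8, 12, len(idx))
            do_b = rng.uniform(8, 12, len(idx))
            rec = detect_turnover(*_frames(idx, t_s, t_b, do_s, do_b), 2002)
            # oracle: exhaustive day-by-day scan
            hit = None
            for day, ts, tb, ds, db in zip(idx, t_s, t_b, do_s, do_b):
                if day < pd.Timestamp("2001-12-01") or \
                        day > pd.Timestamp("2002-04-30"):
                    continue
                if abs(ts - tb) < 0.5 and abs(ds - db) < 0.1:
                    hit = day
                    break
            if hit is None:
                assert rec.failed
            else:
                assert rec.timing == date_to_timing(2002, hit)

    def test_small_gaps_interpolated_large_gaps_rejected(self):
        idx = _daily(2005, 2006)
        surf, bot = _frames(idx, 8.0, 8.0, 10.0, 10.0)
        small = surf.drop(surf.index[40:44])          # 4-day gap
        rec = detect_turnover(small, bot, 2006)
        assert not rec.failed
        big = surf.drop(surf.index[80:100])           # 20-day gap
        with pytest.raises(ValueError, match="gaps"):
            detect_turnover(big, bot, 2006)

    def test_record_invariant(self):
        with pytest.raises(ValueError):
            TurnoverRecord(year=2000, timing=10, failed=True)


class TestTimingRoundTrip:
    @pytest.mark.parametrize("year,timing", [
        (2008, 41), (2009, 53), (2011, -12), (2012, 59), (2013, 0),
        (2016, 78),
    ])
    def test_lossless_including_leap_years(self, year, timing):
        assert date_to_timing(year, timing_to_date(year, timing)) == timing

    def test_leap_day_maps_correctly(self):
        assert timing_to_date(2008, 59) == pd.Timestamp("2008-02-29")
        assert timing_to_date(2009, 59) == pd.Timestamp("2009-03-01")


class TestCurveShape:
    def test_sharp_drop_and_jump_is_turnover_like(self):
        idx = _daily(2007, 2008)
        target = pd.Timestamp("2008-02-11")
        mixed = idx >= target
        t_b = np.where(mixed, 7.0, 8.0)
        do_b = np.where(mixed, 10.5, 6.0)
        out = curve_shape(pd.Series(t_b, index=idx),
                          pd.Series(do_b, index=idx), 2008)
        assert out["shape"] == "turnover-like"
        assert abs(out["turning_point"] - 41) <= 7

    def test_agrees_with_threshold_detector_on_simulated_winters(
            self, biwa_run_6y):
        # the two criteria (threshold detector vs T-DO curve shape) should
        # agree on at least 80% of simulated winters
        from monomict.mixing import detect_turnover_series
        _, out = biwa_run_6y
        turn = detect_turnover_series(out)
        agree = 0
        for i, year in enumerate(turn["year"]):
            s = curve_shape(out.bottom("temp"), out.bottom("do"), int(year))
            if (s["shape"] == "turnover-like") == \
                    (not bool(turn["failed"].iloc[i])):
                agree += 1
        assert agree / len(turn) >= 0.8

    def test_monotone_co_rise_is_straight_line(self):
        idx = _daily(2008, 2009)
        ramp = np.linspace(0, 1, len(idx))
        out = curve_shape(pd.Series(7.0 + 2 * ramp, index=idx),
                          pd.Series(5.0 + 3 * ramp, index=idx), 2009)
        assert out["shape"] == "straight-line"
        assert out["turning_point"] is None


class TestRmseNrmse:
    def test_identical_series_score_zero(self):
        idx = pd.date_range("2000-01-01", periods=20)
        s = pd.Series(np.linspace(5, 15, 20), index=idx)
        m = rmse_nrmse(s, s)
        assert m.rmse == 0.0 and m.nrmse == 0.0

    def test_textbook_arithmetic(self):
        idx = pd.date_range("2000-01-01", periods=3)
        obs = pd.Series([1.0, 2.0, 3.0], index=idx)
        mod = pd.Series([2.0, 3.0, 4.0], index=idx)
        m = rmse_nrmse(obs, mod)
        assert m.rmse == pytest.approx(1.0)
        assert m.nrmse == pytest.approx(0.5)

    def test_matches_spreadsheet_style_oracle(self, rng):
        idx = pd.date_range("2000-01-01", periods=50)
        obs = pd.Series(rng.normal(10, 2, 50), index=idx)
        mod = pd.Series(rng.normal(10, 2, 50), index=idx)
        m = rmse_nrmse(obs, mod)
        # independent arithmetic
        sq = [(o - v) ** 2 for o, v in zip(obs, mod)]
        rmse = (sum(sq) / len(sq)) ** 0.5
        assert m.rmse == pytest.approx(rmse, rel=1e-12)
        assert m.nrmse == pytest.approx(rmse / (obs.max() - obs.min()),
                                        rel=1e-12)

    def test_nearest_timestamp_matching(self):
        obs = pd.Series([5.0, 6.0],
                        index=pd.to_datetime(["2000-01-02", "2000-01-10"]))
        mod = pd.Series(np.arange(12, dtype=float),
                        index=pd.date_range("2000-01-01", periods=12))
        m = rmse_nrmse(obs, mod)
        # pairs: (5, 1.0) and (6, 9.0)
        assert m.rmse == pytest.approx(np.sqrt(((5 - 1) ** 2
                                                + (6 - 9) ** 2) / 2))

    def test_zero_range_flagged(self):
        idx = pd.date_range("2000-01-01", periods=5)
        obs = pd.Series(7.0, index=idx)
        with pytest.warns(UserWarning, match="zero observation range"):
            m = rmse_nrmse(obs, pd.Series(8.0, index=idx))
        assert m.nrmse is None


class TestHypoxiaIndex:
    def test_constant_series_picks_first_day(self):
        idx = pd.date_range("2003-01-01", "2003-12-31")
        out = annual_hypoxia_index(pd.Series(8.0, index=idx))
        assert out.loc[0, "min_do"] == 8.0
        assert out.loc[0, "day"] == 0        # Jan 1, first-occurrence tie-break

    def test_single_dip_located(self):
        idx = pd.date_range("2008-01-01", "2008-12-31")
        s = pd.Series(9.0, index=idx)
        s[pd.Timestamp("2008-09-10")] = 2.0
        out = annual_hypoxia_index(s)
        assert out.loc[0, "min_do"] == 2.0
        assert out.loc[0, "day"] == 253

    def test_matches_brute_force_scan(self, rng):
        idx = pd.date_range("2001-01-01", "2002-12-31")
        s = pd.Series(rng.uniform(2, 12, len(idx)), index=idx)
        out = annual_hypoxia_index(s).set_index("year")
        for year in (2001, 2002):
            sub = s[s.index.year == year]
            best, best_day = np.inf, None
            for day, v in sub.items():
                if v < best:
                    best, best_day = v, day
            assert out.loc[year, "min_do"] == pytest.approx(best)
            assert out.loc[year, "day"] == date_to_timing(year, best_day)

    def test_partial_years_excluded_with_warning(self):
        idx = pd.date_range("2004-06-01", "2005-12-31")
        with pytest.warns(UserWarning, match="2004"):
            out = annual_hypoxia_index(pd.Series(7.0, index=idx))
        assert list(out["year"]) == [2005]


class TestObservedCriterion:
    def test_constant_in_band_detects_first_window_day(self):
        idx = pd.date_range("2000-10-01", "2001-05-31", freq="7D")
        out = observed_turnover_criterion(pd.Series(10.5, index=idx),
                                          pd.Series(10.5, index=idx))
        row = out.set_index("year").loc[2001]
        assert row["detected"]
        assert row["date"] == idx[idx >= pd.Timestamp("2000-12-01")][0]

    def test_bottom_below_band_never_detects(self):
        idx = pd.date_range("2000-10-01", "2001-05-31", freq="7D")
        out = observed_turnover_criterion(pd.Series(10.5, index=idx),
                                          pd.Series(9.5, index=idx))
        assert not out.set_index("year").loc[2001, "detected"]

    def test_matches_brute_force_scan(self, rng):
        idx = pd.date_range("2000-10-01", "2001-05-31", freq="3D")
        s = pd.Series(rng.uniform(9, 12, len(idx)), index=idx)
        b = pd.Series(rng.uniform(9, 12, len(idx)), index=idx)
        out = observed_turnover_criterion(s, b).set_index("year")
        hit = None
        for day in idx:
            if day < pd.Timestamp("2000-12-01") or \
                    day > pd.Timestamp("2001-04-30"):
                continue
            if 10 <= s[day] <= 11 and 10 <= b[day] <= 11:
                hit = day
                break
        if hit is None:
            assert not out.loc[2001, "detected"]
        else:
            assert out.loc[2001, "date"] == hit
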