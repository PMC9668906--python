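"""Turnover detection, validation metrics and hypoxia indices.

The winter overturn of a monomictic lake is detected from daily surface and
bottom series by the joint criterion |ΔT| < 0.5 °C and |ΔDO| < 0.1 mg/L,
with timing reported as integer days past January 1 of the labelled year
(a December detection maps to a negative day number). A secondary
temperature-versus-DO curve-shape classifier cross-checks the detector, and
RMSE/NRMSE metrics support validation against monitoring series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: default detection thresholds (ΔT °C, ΔDO mg/L)
DEFAULT_THRESHOLDS = (0.5, 0.1)
#: default search window: Dec 1 of the preceding year to Apr 30
WINDOW_START = (12, 1)
WINDOW_END = (4, 30)


@dataclass(frozen=True)
class TurnoverRecord:
    """Per-year turnover outcome.

    ``timing`` is days past January 1 of ``year`` (Jan 1 = 0; December
    detections are negative); exactly one of ``timing``/``failed`` is
    meaningful. ``delta_t``/``delta_do`` are the criterion values on the
    detection day.
    """

    year: int
    timing: int | None
    failed: bool
    delta_t: float | None = None
    delta_do: float | None = None
    window: tuple = (WINDOW_START, WINDOW_END)

    def __post_init__(self):
        if self.failed != (self.timing is None):
            raise ValueError("timing must be present exactly when not failed")

    @property
    def date(self):
        """Calendar date of the detection (lossless round-trip of timing)."""
        if self.failed:
            return None
        return pd.Timestamp(self.year, 1, 1) + pd.Timedelta(days=self.timing)


def timing_to_date(year: int, timing: int) -> pd.Timestamp:
    """Days-past-Jan-1 → calendar date (negative = December of year−1)."""
    return pd.Timestamp(year, 1, 1) + pd.Timedelta(days=int(timing))


def date_to_timing(year: int, date) -> int:
    """Calendar date → days past Jan 1 of ``year`` (leap-safe)."""
    return int((pd.Timestamp(date) - pd.Timestamp(year, 1, 1)).days)


@dataclass(frozen=True)
class ValidationMetrics:
    """RMSE and range-normalised RMSE of model vs observations."""

    variable: str
    n: int
    rmse: float
    nrmse: float | None


def _window_index(index: pd.DatetimeIndex, year: int) -> pd.DatetimeIndex:
    lo = pd.Timestamp(year - 1, *WINDOW_START)
    hi = pd.Timestamp(year, *WINDOW_END)
    return index[(index >= lo) & (index <= hi)]


def _prepare(series: pd.Series, window: pd.DatetimeIndex,
             max_gap_days: int = 7) -> pd.Series:
    """Reindex onto the daily window, filling gaps ≤ ``max_gap_days`` by
    linear interpolation; larger gaps are a data error."""
    s = series.dropna().sort_index()
    covered = s.index.intersection(window)
    if len(covered) == 0:
        raise ValueError("series does not cover the search window")
    daily = pd.date_range(window[0], window[-1], freq="D")
    out = s.reindex(s.index.union(daily)).interpolate(
        method="time", limit=max_gap_days, limit_area="inside")
    out = out.reindex(daily)
    if out.isna().any():
        raise ValueError(
            "series has gaps longer than "
            f"{max_gap_days} days inside the search window")
    return out


def detect_turnover(surface: pd.DataFrame, bottom: pd.DataFrame, year: int,
                    thresholds: tuple = DEFAULT_THRESHOLDS) -> TurnoverRecord:
    """First day in the Dec 1 → Apr 30 window where the surface–bottom
    temperature and DO differences both fall inside the thresholds.

    ``surface``/``bottom`` are daily frames with columns ``temp`` and ``do``
    indexed by date. Small gaps (≤ 7 days) are interpolated. Returns a
    failed record when no day satisfies the joint criterion.
    """
    t_thr, do_thr = thresholds
    full = pd.date_range(pd.Timestamp(year - 1, *WINDOW_START),
                         pd.Timestamp(year, *WINDOW_END), freq="D")
    ts = _prepare(surface["temp"], full)
    tb = _prepare(bottom["temp"], full)
    ds = _prepare(surface["do"], full)
    db = _prepare(bottom["do"], full)
    dt_abs = (ts - tb).abs()
    ddo_abs = (ds - db).abs()
    hit = (dt_abs < t_thr) & (ddo_abs < do_thr)
    if not hit.any():
        return TurnoverRecord(year=year, timing=None, failed=True)
    day = hit.idxmax()
    return TurnoverRecord(year=year, timing=date_to_timing(year, day),
                          failed=False, delta_t=float(dt_abs[day]),
                          delta_do=float(ddo_abs[day]))


def curve_shape(bottom_temp: pd.Series, bottom_do: pd.Series, year: int,
                dt_drop: float = 0.05, do_jump: float = 0.5,
                span_days: int = 14) -> dict:
    """Classify the bottom (T, DO) winter trajectory.

    A turnover-like shape has a turning point: a day on which, within the
    trailing ``span_days`` window, bottom temperature fell by at least
    ``dt_drop`` °C while bottom DO rose by at least ``do_jump`` mg/L —
    the signature of cold oxygenated surface water arriving at depth. A
    relatively straight line (no such day) indicates a failed turnover.
    Secondary diagnostic cross-checking :func:`detect_turnover`. The DO
    jump carries the discrimination; the temperature magnitude is small
    because a deep hypolimnion is already near the winter mixed
    temperature when overturn completes.
    """
    full = pd.date_range(pd.Timestamp(year - 1, *WINDOW_START),
                         pd.Timestamp(year, *WINDOW_END), freq="D")
    tb = _prepare(bottom_temp, full)
    db = _prepare(bottom_do, full)
    d_t = tb - tb.shift(span_days)
    d_o = db - db.shift(span_days)
    hit = (d_t <= -dt_drop) & (d_o >= do_jump)
    if hit.any():
        day = hit.idxmax()
        return {"shape": "turnover-like",
                "turning_point": date_to_timing(year, day)}
    return {"shape": "straight-line", "turning_point": None}


def rmse_nrmse(obs: pd.Series, model: pd.Series, variable: str = "",
               tolerance_days: int = 3) -> ValidationMetrics:
    """RMSE and NRMSE (RMSE over the observed range) of matched pairs.

    Pairs are matched by nearest timestamp within ``tolerance_days``. NRMSE
    is ``None`` (flagged) when the observations have zero range.
    """
    o = obs.dropna().sort_index()
    m = model.dropna().sort_index()
    pairs = pd.merge_asof(
        o.rename("obs").reset_index().rename(columns={o.index.name or "index":
                                                      "time"}),
        m.rename("mod").reset_index().rename(columns={m.index.name or "index":
                                                      "time"}),
        on="time", direction="nearest",
        tolerance=pd.Timedelta(days=tolerance_days)).dropna()
    if len(pairs) < 2:
        raise ValueError("need at least 2 matched observation/model pairs")
    err = pairs["obs"] - pairs["mod"]
    rmse = float(np.sqrt((err ** 2).mean()))
    rng = float(pairs["obs"].max() - pairs["obs"].min())
    if rng == 0.0:
        warnings.warn("zero observation range: NRMSE undefined")
        nrmse = None
    else:
        nrmse = rmse / rng
    return ValidationMetrics(variable=variable, n=len(pairs), rmse=rmse,
                             nrmse=nrmse)


def annual_hypoxia_index(bottom_do: pd.Series) -> pd.DataFrame:
    """Annual minimum bottom DO [mg/L] and its day of year (Jan 1 = 0).

    Partial calendar years are excluded with a warning; ties break to the
    first occurrence.
    """
    s = bottom_do.dropna().sort_index()
    rows = []
    for year, grp in s.groupby(s.index.year):
        n_days = pd.Timestamp(year, 12, 31).dayofyear
        if len(grp) < n_days:
            warnings.warn(f"year {year} covers only {len(grp)} days; excluded")
            continue
        day = grp.idxmin()
        rows.append({"year": int(year), "min_do": float(grp.min()),
                     "day": date_to_timing(year, day)})
    return pd.DataFrame(rows, columns=["year", "min_do", "day"])


def observed_turnover_criterion(surface_do: pd.Series, bottom_do: pd.Series,
                                lo: float = 10.0, hi: float = 11.0
                                ) -> pd.DataFrame:
    """Observation-style criterion: first cold-season date with both the
    surface and bottom DO inside [lo, hi] mg/L.

    Accepts weekly-or-finer series; no interpolation — the criterion is
    evaluated on shared observation dates. One row per labelled year with
    ``detected``/``date``/``timing``.
    """
    s = surface_do.dropna().sort_index()
    b = bottom_do.dropna().sort_index()
    shared = s.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("surface and bottom DO series share no dates")
    years = sorted(set(shared.year) | set(shared.year + 1))
    rows = []
    for year in years:
        win = _window_index(shared, year)
        if len(win) == 0:
            continue
        ok = (s[win].between(lo, hi) & b[win].between(lo, hi))
        if ok.any():
            day = ok.idxmax()
            rows.append({"year": year, "detected": True, "date": day,
                         "timing": date_to_timing(year, day)})
        else:
            rows.append({"year": year, "detected": False, "date": None,
                         "timing": None})
    return pd.DataFrame(rows, columns=["year", "detected", "date", "timing"])


def detect_turnover_series(simout, years=None,
                           thresholds: tuple = DEFAULT_THRESHOLDS
                           ) -> pd.DataFrame:
    """Run :func:`detect_turnover` on every detectable year of a simulation.

    Returns one row per year with timing (days past Jan 1), the failure
    flag, and the criterion values at detection.
    """
    surf = pd.DataFrame({"temp": simout.surface("temp"),
                         "do": simout.surface("do")})
    bot = pd.DataFrame({"temp": simout.bottom("temp"),
                        "do": simout.bottom("do")})
    idx = surf.index
    if years is None:
        years = [y for y in sorted(set(idx.year))
                 if pd.Timestamp(y, *WINDOW_END) <= idx[-1]
                 and pd.Timestamp(y - 1, *WINDOW_START) >= idx[0]]
    rows = []
    for y in years:
        rec = detect_turnover(surf, bot, y, thresholds)
        rows.append({"year": y, "timing": rec.timing, "failed": rec.failed,
                     "delta_t": rec.delta_t, "delta_do": rec.delta_do})
    return pd.DataFrame(rows, columns=["year", "timing", "failed",
                                       "delta_t", "delta_do"])
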