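"""Cross-year statistics: climate-predictor aggregation, bagged-forest
variable importance for turnover timing, and the hypoxia–phosphorus
regressions with a period split.

The importance statistics mirror the classic regression random-forest
outputs: out-of-bag permutation %IncMSE, summed node-purity (impurity)
decrease, and out-of-bag variance explained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.tree import DecisionTreeRegressor

from .mixing import detect_turnover_series

PREDICTORS = ["AT", "pptn", "CC", "DD", "POC", "WS"]


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary-least-squares summary for one fitted relationship."""

    slope: float
    intercept: float
    r2: float
    n: int
    ci_low: float
    ci_high: float
    resid_sd: float


@dataclass(frozen=True)
class ImportanceTable:
    """Forest variable-importance output.

    ``pct_inc_mse``: per-predictor % increase in out-of-bag MSE after
    permuting that predictor; ``node_purity``: summed impurity decrease over
    all trees; ``var_explained``: out-of-bag variance explained [%].
    """

    pct_inc_mse: pd.Series
    node_purity: pd.Series
    var_explained: float
    n_trees: int
    seed: int


def aggregate_predictors(simout, meteo: pd.DataFrame,
                         mode: str = "cold_season") -> pd.DataFrame:
    """One modelling row per year: climate and column predictors plus the
    turnover-timing response.

    ``cold_season`` aggregates Nov 1 (Y−1) → Apr 30 (Y); ``annual`` uses
    calendar-year Y means. Predictors: AT [°C], pptn [mm/day], CC
    [fraction], WS [m/s, land-station values], DD [bottom−surface density,
    kg/m³], POC [surface POC, mgC/m³]. Years whose turnover failed keep the
    row with ``timing`` = NaN and ``failed`` = True; incomplete seasons are
    dropped with a warning-free skip.
    """
    if mode not in ("cold_season", "annual"):
        raise ValueError("mode must be 'cold_season' or 'annual'")
    met = meteo.copy()
    met["date"] = pd.to_datetime(met["date"])
    met = met.set_index("date")
    dd = simout.bottom("density") - simout.surface("density")
    poc = simout.surface("poc")
    turn = detect_turnover_series(simout).set_index("year")

    rows = []
    for year in turn.index:
        if mode == "cold_season":
            lo, hi = pd.Timestamp(year - 1, 11, 1), pd.Timestamp(year, 4, 30)
        else:
            lo, hi = pd.Timestamp(year, 1, 1), pd.Timestamp(year, 12, 31)
        m_win = met.loc[lo:hi]
        expected = (hi - lo).days + 1
        if len(m_win) < expected or len(dd.loc[lo:hi]) < expected:
            continue
        rows.append({
            "year": year,
            "AT": m_win["air_temp_c"].mean(),
            "pptn": m_win["precip_mm"].mean(),
            "CC": m_win["cloud_frac"].mean(),
            "DD": dd.loc[lo:hi].mean(),
            "POC": poc.loc[lo:hi].mean(),
            "WS": m_win["wind_ms"].mean(),
            "timing": turn.loc[year, "timing"],
            "failed": bool(turn.loc[year, "failed"]),
        })
    return pd.DataFrame(rows, columns=["year"] + PREDICTORS
                        + ["timing", "failed"]).set_index("year")


# ---------------------------------------------------------------------------
# bagged regression forest with OOB permutation importance

def forest_importance(table: pd.DataFrame, n_trees: int = 500,
                      seed: int = 0, predictors: list | None = None,
                      response: str = "timing",
                      include_failed: bool = False) -> ImportanceTable:
    """Variable importance of the predictors for turnover timing.

    Fits a bagged ensemble of regression trees (max_features = p/3, the
    regression-forest convention) and reports, per predictor, the
    out-of-bag permutation %IncMSE and the summed node-purity decrease,
    plus the out-of-bag variance explained. Failed-turnover years are
    excluded from the response unless ``include_failed`` (censored mode:
    timing set to the window end, day 120).
    """
    preds = predictors or [c for c in PREDICTORS if c in table.columns]
    if len(preds) < 2:
        raise ValueError("need at least 2 predictors")
    df = table.copy()
    if "failed" in df.columns:
        if include_failed:
            df.loc[df["failed"].astype(bool), response] = 120.0
        else:
            df = df[~df["failed"].astype(bool)]
    df = df.dropna(subset=preds + [response])
    if len(df) < 8:
        raise ValueError(
            f"need at least 8 modelling rows, got {len(df)}")
    x = df[preds].to_numpy(float)
    y = df[response].to_numpy(float)
    n, p = x.shape
    rng = np.random.default_rng(seed)
    max_features = max(1, p // 3)

    oob_sum = np.zeros(n)
    oob_cnt = np.zeros(n)
    perm_sum = np.zeros((p, n))
    perm_cnt = np.zeros((p, n))
    purity = np.zeros(p)
    for t in range(n_trees):
        idx = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), idx)
        tree = DecisionTreeRegressor(
            max_features=max_features,
            random_state=int(rng.integers(0, 2 ** 31 - 1)))
        tree.fit(x[idx], y[idx])
        purity += _node_purity_decrease(tree, p)
        if len(oob) == 0:
            continue
        oob_sum[oob] += tree.predict(x[oob])
        oob_cnt[oob] += 1
        for j in range(p):
            xp = x[oob].copy()
            xp[:, j] = xp[rng.permutation(len(oob)), j]
            perm_sum[j, oob] += tree.predict(xp)
            perm_cnt[j, oob] += 1

    seen = oob_cnt > 0
    mse_oob = float(np.mean((y[seen] - oob_sum[seen] / oob_cnt[seen]) ** 2))
    pct = {}
    for j, name in enumerate(preds):
        sj = perm_cnt[j] > 0
        mse_perm = float(np.mean(
            (y[sj] - perm_sum[j, sj] / perm_cnt[j, sj]) ** 2))
        pct[name] = 100.0 * (mse_perm - mse_oob) / mse_oob
    var_y = float(np.var(y))
    var_explained = 100.0 * (1.0 - mse_oob / var_y) if var_y > 0 else 0.0
    return ImportanceTable(
        pct_inc_mse=pd.Series(pct),
        node_purity=pd.Series(purity, index=preds),
        var_explained=var_explained, n_trees=n_trees, seed=seed)


def _node_purity_decrease(tree: DecisionTreeRegressor, p: int) -> np.ndarray:
    """Unnormalised summed impurity decrease per feature (node purity)."""
    t = tree.tree_
    out = np.zeros(p)
    for node in range(t.node_count):
        left, right = t.children_left[node], t.children_right[node]
        if left == -1:
            continue
        w = t.weighted_n_node_samples
        dec = (w[node] * t.impurity[node]
               - w[left] * t.impurity[left]
               - w[right] * t.impurity[right])
        out[t.feature[node]] += dec
    return out


# ---------------------------------------------------------------------------
# linear regressions

def linear_fit(x, y, alpha: float = 0.05) -> RegressionResult:
    """OLS fit of y on x with a t-distribution slope confidence interval."""
    x_arr = np.asarray(x, float)
    y_arr = np.asarray(y, float)
    mask = np.isfinite(x_arr) & np.isfinite(y_arr)
    x_arr, y_arr = x_arr[mask], y_arr[mask]
    if len(x_arr) < 3:
        raise ValueError("need at least 3 finite (x, y) pairs")
    if np.ptp(x_arr) == 0:
        raise ValueError("x has zero variance: singular fit")
    model = sm.OLS(y_arr, sm.add_constant(x_arr)).fit()
    ci = model.conf_int(alpha=alpha)[1]
    return RegressionResult(
        slope=float(model.params[1]), intercept=float(model.params[0]),
        r2=float(model.rsquared), n=int(model.nobs),
        ci_low=float(ci[0]), ci_high=float(ci[1]),
        resid_sd=float(np.sqrt(model.mse_resid)))


def period_split_fit(x, y, years, split_year: int = 1980) -> dict:
    """Independent linear fits before (≤ ``split_year``) and after.

    Mirrors the eutrophication-era analysis: the DIP–DO relationship is fit
    separately for the high-loading years and the post-load-reduction
    years; the boundary year belongs to "before".
    """
    yrs = np.asarray(years)
    x_arr = np.asarray(x, float)
    y_arr = np.asarray(y, float)
    before = yrs <= split_year
    out = {}
    for label, mask in (("before", before), ("after", ~before)):
        if mask.sum() < 3:
            raise ValueError(
                f"period '{label}' has {int(mask.sum())} years; need >= 3")
        out[label] = linear_fit(x_arr[mask], y_arr[mask])
    return out
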