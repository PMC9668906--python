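"""Coupled physics–ecosystem column simulator.

Marches the layered state through multi-year scenarios with operator
splitting (surface heat → vertical mixing of heat and tracers → convective
adjustment → sinking → biochemical reactions → reaeration/sediment →
river exchange), archives daily means, and keeps a boundary-flux ledger so
whole-run heat and elemental budgets can be closed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import _kernels as K
from .ecosystem import EcoParams, N_TO_C, P_TO_C, O2_TO_C, do_saturation
from .forcing import (RiverConfig, ScenarioConfig, generate_loading,
                      generate_meteo, generate_river_inputs)
from .physics import ColumnGrid, PhysicsParams

log = logging.getLogger("monomict")

TRACER_NAMES = ("phy", "zoo", "poc", "din", "dip", "do", "dic")


@dataclass
class InitialState:
    """Column initial condition (winter-mixed defaults, Jan 1 start)."""

    temperature: float = 8.0    # °C, isothermal
    phy: float = 10.0           # mgC/m³
    zoo: float = 2.0            # mgC/m³
    poc: float = 20.0           # mgC/m³
    din: float = 150.0          # µgN/L
    dip: float = 5.0            # µgP/L
    do: float | None = None     # mg/L; None -> saturation at temperature
    sed_c: float = 50.0         # gC/m² active sediment organic carbon

    def build(self, n_layers: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        temp = np.full(n_layers, float(self.temperature))
        tr = np.zeros((K.N_TRACERS, n_layers))
        do0 = self.do if self.do is not None else do_saturation(self.temperature)
        for i, v in enumerate((self.phy, self.zoo, self.poc, self.din,
                               self.dip, do0, 0.0)):
            tr[i, :] = v
        sed = np.array([self.sed_c, self.sed_c * N_TO_C, self.sed_c * P_TO_C])
        return temp, tr, sed


def stability_check(dt: float, grid: ColumnGrid,
                    eco_params: EcoParams | None = None,
                    max_dt: float = 3600.0) -> list[str]:
    """Return the list of violated step-size constraints (empty = ok).

    Checks the sinking CFL bound (w·dt ≤ dz, boundary equality allowed),
    the forward-Euler positivity bound on the fastest biochemical rate, and
    the configured maximum step.
    """
    ep = eco_params or EcoParams()
    problems = []
    if dt <= 0:
        problems.append(f"dt = {dt} s must be positive")
        return problems
    if dt > max_dt:
        problems.append(f"dt = {dt} s exceeds the configured maximum {max_dt} s")
    dt_days = dt / 86400.0
    for name, w in (("w_sink_phy", ep.w_sink_phy), ("w_sink_poc", ep.w_sink_poc)):
        if w * dt_days > grid.dz:
            problems.append(
                f"sinking CFL violated for {name}: {w} m/day × dt = "
                f"{w * dt_days:.3g} m > dz = {grid.dz} m")
    warm = ep.q10 ** ((30.0 - 20.0) / 10.0)
    r_max = warm * max(ep.mu_max, ep.graze_max, ep.decomposition,
                       ep.resp_phy + ep.mort_phy, ep.resp_zoo + ep.mort_zoo)
    if r_max * dt_days > 0.5:
        problems.append(
            f"ecology positivity bound: fastest rate × dt = "
            f"{r_max * dt_days:.3g} > 0.5")
    return problems


@dataclass
class SimOutput:
    """Daily time × depth archive of a column run.

    ``data[var]`` is an (n_days, n_layers) array of daily means for var in
    temp, density, phy, zoo, poc, din, dip, do, dic. ``sediment`` holds the
    end-of-day C/N/P pools, ``ledger`` the per-day boundary fluxes, and the
    ``final_*``/``initial_*`` state snapshots support budget closure.
    ``meta`` records the config hash, seed and package version so a run can
    be reproduced bit-identically.
    """

    time: pd.DatetimeIndex
    depths: np.ndarray
    data: dict
    sediment: pd.DataFrame
    ledger: pd.DataFrame
    meta: dict
    initial_temp: np.ndarray
    initial_tracers: np.ndarray
    initial_sed: np.ndarray
    final_temp: np.ndarray
    final_tracers: np.ndarray
    final_sed: np.ndarray
    dz: float = 2.5
    cp_water: float = 4186.0

    def surface(self, var: str) -> pd.Series:
        return pd.Series(self.data[var][:, 0], index=self.time, name=var)

    def bottom(self, var: str) -> pd.Series:
        return pd.Series(self.data[var][:, -1], index=self.time, name=var)

    def to_frame(self) -> pd.DataFrame:
        """Long format: time, depth_m, var, value."""
        frames = []
        for var, arr in self.data.items():
            df = pd.DataFrame(arr, index=self.time, columns=self.depths)
            long = df.stack().rename("value").reset_index()
            long.columns = ["time", "depth_m", "value"]
            long.insert(2, "var", var)
            frames.append(long)
        return pd.concat(frames, ignore_index=True)

    # -- budget accounting ---------------------------------------------------
    def _totals(self, temp, tracers, sed):
        dz = self.dz
        phy, zoo, poc, din, dip, do, dic = tracers
        c = (phy + zoo + poc + dic).sum() * dz + sed[0] * 1000.0
        n = (N_TO_C * (phy + zoo + poc).sum() + din.sum()) * dz + sed[1] * 1000.0
        p = (P_TO_C * (phy + zoo + poc).sum() + dip.sum()) * dz + sed[2] * 1000.0
        heat = K.RHO0 * self.cp_water * temp.sum() * dz
        o2 = do.sum() * dz
        dic_tot = dic.sum() * dz
        return heat, c, n, p, o2, dic_tot

    def budget_residuals(self) -> dict:
        """Relative whole-run closure residuals for heat, C, N, P and O2.

        Each residual is |Δstock − Σ boundary fluxes| normalised by the
        larger of the initial stock and the gross boundary exchange.
        """
        led = self.ledger.sum()
        h0, c0, n0, p0, o0, dic0 = self._totals(
            self.initial_temp, self.initial_tracers, self.initial_sed)
        h1, c1, n1, p1, o1, dic1 = self._totals(
            self.final_temp, self.final_tracers, self.final_sed)

        def rel(resid, stock, flux):
            return abs(resid) / max(abs(stock), abs(flux), 1e-30)

        res = {}
        res["heat"] = rel(h1 - h0 - led["heat_surf"] - led["heat_riv"],
                          h0, abs(led["heat_surf"]) + abs(led["heat_riv"]))
        res["carbon"] = rel(c1 - c0 - led["c_riv"], c0, abs(led["c_riv"]))
        res["nitrogen"] = rel(n1 - n0 - led["n_riv"], n0, abs(led["n_riv"]))
        res["phosphorus"] = rel(p1 - p0 - led["p_riv"], p0, abs(led["p_riv"]))
        # water-column biological C turnover, net of sediment and river DIC
        sed_dic = (-led["o2_sed"] + led["o2_anaer"]) * 1000.0 / O2_TO_C
        bio_c = (dic1 - dic0) - sed_dic - led["dic_riv"]
        o2_fluxes = (led["o2_air"] + led["o2_sed"] + led["o2_vent"]
                     + led["o2_riv"])
        res["oxygen"] = rel(o1 - o0 + O2_TO_C * bio_c / 1000.0 - o2_fluxes,
                            o0, abs(led["o2_air"]) + abs(led["o2_sed"]))
        return res


_LEDGER_COLS = ["heat_surf", "heat_riv", "c_riv", "n_riv", "p_riv", "o2_air",
                "o2_sed", "o2_vent", "o2_riv", "o2_anaer", "dic_riv"]


def _config_hash(payload: dict) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run(scenario: ScenarioConfig | None = None, *,
        meteo: pd.DataFrame | None = None,
        river: pd.DataFrame | None = None,
        grid: ColumnGrid | None = None,
        physics_params: PhysicsParams | None = None,
        eco_params: EcoParams | None = None,
        river_config: RiverConfig | None = None,
        init: InitialState | None = None,
        dt: float = 600.0,
        archive_every: int = 1,
        eco_on: bool = True,
        rivers_on: bool = True,
        suppress_mixing: bool = False,
        check: bool = True,
        verbose: bool = False) -> SimOutput:
    """Run the coupled column model and return the daily archive.

    Either pass a ``scenario`` (forcing and river inputs are generated from
    it, deterministically in its seed) or explicit ``meteo`` (and optional
    ``river``) DataFrames. ``archive_every`` keeps every k-th daily mean; it
    never changes the dynamics. ``suppress_mixing`` disables convective
    adjustment and deep wind stirring — the artificial
    permanently-stratified counterfactual. Raises on NaN/Inf with the first
    offending day and layer.
    """
    grid = grid or ColumnGrid()
    pp = physics_params or PhysicsParams()
    ep = eco_params or EcoParams()
    init = init or InitialState()
    if meteo is None:
        if scenario is None:
            raise ValueError("provide a scenario or an explicit meteo table")
        meteo = generate_meteo(scenario)
        if rivers_on and river is None:
            river = generate_river_inputs(meteo, generate_loading(scenario),
                                          river_config)
    if check:
        problems = stability_check(dt, grid, ep)
        if problems:
            raise ValueError("stability check failed: " + "; ".join(problems))
    if archive_every < 1:
        raise ValueError("archive_every must be >= 1")

    dates = pd.DatetimeIndex(pd.to_datetime(meteo["date"]))
    nd = len(dates)
    forc = meteo[["air_temp_c", "wind_ms", "cloud_frac", "precip_mm",
                  "shortwave_wm2"]].to_numpy(float)
    if rivers_on and river is not None:
        riv = river[["flow_m3d", "temp_c", "din_mgm3", "dip_mgm3",
                     "poc_mgm3"]].to_numpy(float)
        if len(riv) != nd:
            raise ValueError("meteo and river tables cover different days")
    else:
        riv = np.zeros((nd, 5))

    temp, tracers, sed = init.build(grid.n_layers)
    t0, tr0, sed0 = temp.copy(), tracers.copy(), sed.copy()
    n_sub = max(1, int(round(86400.0 / dt)))
    arch_t = np.empty((nd, grid.n_layers))
    arch_tr = np.empty((K.N_TRACERS, nd, grid.n_layers))
    arch_sed = np.empty((nd, 3))
    ledger = np.zeros((nd, K.N_LEDGER))

    years = dates.year.to_numpy()
    starts = np.concatenate([[0], np.flatnonzero(np.diff(years)) + 1, [nd]])
    for a, b in zip(starts[:-1], starts[1:]):
        K.simulate_days(temp, tracers, sed, forc[a:b], riv[a:b],
                        pp.to_array(), ep.to_array(), grid.dz, dt, n_sub,
                        eco_on, suppress_mixing,
                        arch_t[a:b], arch_tr[:, a:b, :], arch_sed[a:b],
                        ledger[a:b])
        if verbose:
            log.info("year %d done: surf T=%.2f °C bottom T=%.2f °C "
                     "bottom DO=%.2f mg/L", years[a], temp[0], temp[-1],
                     tracers[K.I_DO, -1])

    for name, arr in (("temperature", arch_t), ("tracers", arch_tr)):
        bad = ~np.isfinite(arr)
        if bad.any():
            idx = np.argwhere(bad)[0]
            raise RuntimeError(
                f"numerical instability: non-finite {name} first at "
                f"day index {idx[-2]}, layer {idx[-1]}")

    density = np.empty_like(arch_t)
    flat = arch_t.ravel()
    dflat = density.ravel()
    K.water_density_profile(flat, dflat)

    keep = slice(None, None, archive_every)
    data = {"temp": arch_t[keep], "density": density[keep]}
    for i, name in enumerate(TRACER_NAMES):
        data[name] = arch_tr[i][keep]

    payload = {
        "scenario": asdict(scenario) if scenario is not None else None,
        "physics": asdict(pp), "ecology": asdict(ep), "init": asdict(init),
        "grid": asdict(grid), "dt": dt, "eco_on": eco_on,
        "rivers_on": rivers_on, "suppress_mixing": suppress_mixing,
    }
    from . import __version__
    meta = {"config_hash": _config_hash(payload), "version": __version__,
            "seed": scenario.seed if scenario is not None else None,
            "dt": dt, "n_days": nd, "archive_every": archive_every}
    return SimOutput(
        time=dates[keep], depths=grid.mid_depths, data=data,
        sediment=pd.DataFrame(arch_sed[keep], index=dates[keep],
                              columns=["sed_c", "sed_n", "sed_p"]),
        ledger=pd.DataFrame(ledger, index=dates, columns=_LEDGER_COLS),
        meta=meta, initial_temp=t0, initial_tracers=tr0, initial_sed=sed0,
        final_temp=temp, final_tracers=tracers, final_sed=sed,
        dz=grid.dz, cp_water=pp.cp_water)
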