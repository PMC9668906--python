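"""Synthetic meteorological forcing and nutrient-loading scenarios.

Emulates the statistical structure of the multi-decadal inputs that drive
the lake column: daily meteorology with the climatology of a mid-latitude
Japanese land station (annual mean air temperature ≈ 14 °C, annual
precipitation ≈ 1700 mm), an optional interannual warming trend, AR(1)
synoptic noise, and an external TN/TP loading history with the classic
eutrophication shape — rise to a mid-1970s peak, steep decline from 1980 to
2000, and a halving between 2000 and 2010.

Every series is fully determined by the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from .ecosystem import N_TO_C, P_TO_C

METEO_COLUMNS = ["date", "air_temp_c", "wind_ms", "cloud_frac",
                 "precip_mm", "shortwave_wm2"]
LOADING_COLUMNS = ["year", "tn_load", "tp_load"]
RIVER_COLUMNS = ["date", "flow_m3d", "temp_c", "din_mgm3", "dip_mgm3",
                 "poc_mgm3"]

_SOLAR_CONST = 1361.0


@dataclass
class RiverConfig:
    """Aggregated river-source configuration.

    The many real tributaries are collapsed to a configurable set of
    aggregate sources (area weights); only the total matters to a 1-D
    column, the weights support per-river breakdowns.
    """

    catchment_area: float = 3.8e9       # m²
    runoff_coeff: float = 0.55          # rainfall -> discharge fraction [-]
    baseflow: float = 20.0              # m³/s
    smooth_days: int = 10               # precip -> flow smoothing window
    frac_bioavailable_n: float = 0.6    # TN delivered as DIN [-]
    frac_bioavailable_p: float = 0.6    # TP delivered as DIP [-]
    river_weights: tuple = (0.5, 0.3, 0.2)

    def __post_init__(self):
        if not 0 <= self.frac_bioavailable_n <= 1:
            raise ValueError("frac_bioavailable_n must be in [0, 1]")
        if not 0 <= self.frac_bioavailable_p <= 1:
            raise ValueError("frac_bioavailable_p must be in [0, 1]")


@dataclass
class ScenarioConfig:
    """Forcing-scenario parameters (config block ``scenario:``).

    Each meteorological variable is a sinusoidal climatology plus a linear
    trend (air temperature only, centred on the series midpoint so the
    configured mean is the series mean) plus AR(1) daily anomalies, clipped
    to its physical domain. ``winter_air_offset`` (Dec–Mar) and
    ``winter_wind_multiplier`` (Nov–Apr) are cold-season experiment knobs.
    """

    n_years: int = 5
    start_year: int = 1990
    seed: int = 0
    mean_air_temp: float = 14.0     # °C (annual mean)
    amp_air_temp: float = 11.5      # °C seasonal half-range
    phase_air_temp: float = 25.0    # day-of-year of the minimum
    trend_air_temp: float = 0.0     # °C/decade
    mean_wind: float = 3.2          # m/s (land station)
    amp_wind: float = 0.7           # m/s, winter maximum
    phase_wind: float = 10.0        # day-of-year of the maximum
    mean_cloud: float = 0.65        # fraction
    amp_cloud: float = 0.10
    phase_cloud: float = 15.0       # day-of-year of the maximum
    annual_precip: float = 1700.0   # mm/year
    amp_precip: float = 1.5         # mm/day seasonal half-range
    phase_precip: float = 180.0     # day-of-year of the maximum
    latitude: float = 35.25         # ° N, for clear-sky radiation
    transmissivity: float = 0.75    # clear-sky atmospheric transmissivity
    cloud_attenuation: float = 0.65  # shortwave reduction at full cover
    ar1_phi: float = 0.7            # daily anomaly persistence
    noise_air_temp: float = 1.8     # AR(1) innovation s.d. [°C]
    noise_wind: float = 1.0         # [m/s]
    noise_cloud: float = 0.25       # [fraction]
    noise_precip: float = 0.8       # lognormal AR(1) innovation s.d. [-]
    winter_air_offset: float = 0.0  # added to Dec–Mar air temperature [°C]
    winter_wind_multiplier: float = 1.0  # Nov–Apr wind multiplier [-]
    loading_preset: str = "biwa-history"
    constant_tn: float = 3600.0     # tN/yr for the constant preset
    constant_tp: float = 300.0      # tP/yr for the constant preset

    def __post_init__(self):
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        for name in ("amp_air_temp", "amp_wind", "amp_cloud", "amp_precip",
                     "noise_air_temp", "noise_wind", "noise_cloud",
                     "noise_precip", "annual_precip",
                     "winter_wind_multiplier"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.ar1_phi < 1:
            raise ValueError("ar1_phi must be in (0, 1)")

    @classmethod
    def biwa_like(cls, n_years: int = 5, seed: int = 0,
                  start_year: int = 1990, **overrides) -> "ScenarioConfig":
        """The default study-like scenario (a gentle warming trend on the
        station climatology)."""
        kw = dict(n_years=n_years, seed=seed, start_year=start_year,
                  trend_air_temp=0.2)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown scenario keys: {sorted(unknown)}")
        return cls(**d)


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) anomaly series with innovation s.d. ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    eps = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = eps[0] * sd / np.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + sd * eps[t]
    return x


def clear_sky_radiation(day_of_year: np.ndarray, latitude: float) -> np.ndarray:
    """Daily-mean top-of-atmosphere shortwave [W/m²] at ``latitude``."""
    doy = np.asarray(day_of_year, dtype=float)
    phi = np.deg2rad(latitude)
    decl = np.deg2rad(23.45) * np.sin(2 * np.pi * (284 + doy) / 365.25)
    dr = 1.0 + 0.033 * np.cos(2 * np.pi * doy / 365.25)
    cos_ws = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    ws = np.arccos(cos_ws)
    return (_SOLAR_CONST / np.pi) * dr * (
        ws * np.sin(phi) * np.sin(decl)
        + np.cos(phi) * np.cos(decl) * np.sin(ws))


def generate_meteo(config: ScenarioConfig) -> pd.DataFrame:
    """Daily meteorological forcing (the forcing-CSV schema, one row/day).

    Columns: date, air_temp_c, wind_ms, cloud_frac, precip_mm,
    shortwave_wm2. Shortwave is the clear-sky day-of-year curve attenuated
    by ``1 − cloud_attenuation × cloud``, so cloudy anomalies dim the lake
    consistently. Deterministic given the seed.
    """
    c = config
    dates = pd.date_range(f"{c.start_year}-01-01",
                          f"{c.start_year + c.n_years - 1}-12-31", freq="D")
    n = len(dates)
    doy = dates.day_of_year.to_numpy(float)
    ang = 2 * np.pi / 365.25
    rng = np.random.default_rng(c.seed)
    # independent child streams per variable, in a fixed order
    r_at, r_ws, r_cc, r_pr = rng.spawn(4)

    years_from_mid = (np.arange(n) - (n - 1) / 2) / 365.25
    at = (c.mean_air_temp
          - c.amp_air_temp * np.cos(ang * (doy - c.phase_air_temp))
          + c.trend_air_temp / 10.0 * years_from_mid
          + _ar1(r_at, n, c.ar1_phi, c.noise_air_temp))
    month = dates.month.to_numpy()
    if c.winter_air_offset != 0.0:
        at = at + c.winter_air_offset * np.isin(month, (12, 1, 2, 3))

    ws = (c.mean_wind + c.amp_wind * np.cos(ang * (doy - c.phase_wind))
          + _ar1(r_ws, n, c.ar1_phi, c.noise_wind))
    ws = np.clip(ws, 0.2, None)
    if c.winter_wind_multiplier != 1.0:
        cold = np.isin(month, (11, 12, 1, 2, 3, 4))
        ws = np.where(cold, ws * c.winter_wind_multiplier, ws)

    cc = np.clip(c.mean_cloud
                 + c.amp_cloud * np.cos(ang * (doy - c.phase_cloud))
                 + _ar1(r_cc, n, c.ar1_phi, c.noise_cloud), 0.0, 1.0)

    base = c.annual_precip / 365.25 + c.amp_precip * np.cos(
        ang * (doy - c.phase_precip))
    anom = _ar1(r_pr, n, c.ar1_phi, c.noise_precip)
    var = (c.noise_precip ** 2 / (1.0 - c.ar1_phi ** 2)
           if c.noise_precip > 0 else 0.0)
    precip = np.clip(base, 0.0, None) * np.exp(anom - var / 2.0)

    sw = (clear_sky_radiation(doy, c.latitude) * c.transmissivity
          * (1.0 - c.cloud_attenuation * cc))
    sw = np.clip(sw, 0.0, None)

    return pd.DataFrame({"date": dates, "air_temp_c": at, "wind_ms": ws,
                         "cloud_frac": cc, "precip_mm": precip,
                         "shortwave_wm2": sw})


# ---------------------------------------------------------------------------
# nutrient-loading history

_TP_NODES = [(1900, 200.0), (1955, 200.0), (1975, 1000.0), (1980, 950.0),
             (2000, 320.0), (2010, 160.0), (2100, 160.0)]
_TN_SCALE = 12.0  # TN load = scale × TP shape


def _history_tp(years: np.ndarray) -> np.ndarray:
    xs = np.array([n[0] for n in _TP_NODES], float)
    ys = np.array([n[1] for n in _TP_NODES], float)
    return np.interp(np.asarray(years, float), xs, ys)


def generate_loading(config: ScenarioConfig) -> pd.DataFrame:
    """Annual external TN/TP loads (columns year, tn_load, tp_load).

    The ``biwa-history`` preset is the eutrophication–recovery shape: a
    unimodal curve peaking in 1975, strictly decreasing on 1980–2000, with
    the 2010 load half of the 2000 load; ``constant`` holds the configured
    level; anything else is a configuration error (supply custom loads as a
    DataFrame directly).
    """
    years = np.arange(config.start_year, config.start_year + config.n_years)
    if config.loading_preset == "biwa-history":
        tp = _history_tp(years)
        tn = _TN_SCALE * tp
    elif config.loading_preset == "constant":
        tp = np.full(len(years), float(config.constant_tp))
        tn = np.full(len(years), float(config.constant_tn))
    else:
        raise ValueError(
            f"unknown loading preset {config.loading_preset!r}; "
            "expected 'biwa-history' or 'constant'")
    return pd.DataFrame({"year": years, "tn_load": tn, "tp_load": tp})


def generate_river_inputs(meteo: pd.DataFrame, loading: pd.DataFrame,
                          river_config: RiverConfig | None = None
                          ) -> pd.DataFrame:
    """Daily aggregate river inputs to the column.

    Flow is baseflow plus runoff from smoothed precipitation over the
    catchment; river temperature equals the same-day air temperature
    (floored at 0 °C — river water cannot be colder); nutrient
    concentrations are scaled per calendar year so that the annual mass of
    DIN (DIP) equals the bioavailable fraction of that year's TN (TP) load,
    the remainder of TP entering as Redfield-stoichiometry POC.
    """
    rc = river_config or RiverConfig()
    dates = pd.to_datetime(meteo["date"])
    years = dates.dt.year.to_numpy()
    load_years = loading["year"].to_numpy()
    if not np.all(np.isin(np.unique(years), load_years)):
        missing = sorted(set(years) - set(load_years))
        raise ValueError(f"loading series does not cover years {missing}")

    precip_m = (meteo["precip_mm"].rolling(rc.smooth_days, min_periods=1)
                .mean().to_numpy() / 1000.0)
    flow = rc.baseflow * 86400.0 + rc.runoff_coeff * rc.catchment_area * precip_m

    tn = pd.Series(loading["tn_load"].to_numpy(), index=load_years)
    tp = pd.Series(loading["tp_load"].to_numpy(), index=load_years)
    din = np.empty(len(dates))
    dip = np.empty(len(dates))
    poc = np.empty(len(dates))
    for y in np.unique(years):
        sel = years == y
        q_year = flow[sel].sum()                   # m³ this calendar year
        n_mass = rc.frac_bioavailable_n * tn[y] * 1e9   # mgN
        p_mass = rc.frac_bioavailable_p * tp[y] * 1e9   # mgP
        p_part = (1.0 - rc.frac_bioavailable_p) * tp[y] * 1e9
        din[sel] = n_mass / q_year                  # mgN/m³, constant per year
        dip[sel] = p_mass / q_year
        poc[sel] = p_part / P_TO_C / q_year         # mgC/m³ from P-bound POC

    temp = np.clip(meteo["air_temp_c"].to_numpy(), 0.0, None)
    return pd.DataFrame({"date": dates, "flow_m3d": flow, "temp_c": temp,
                         "din_mgm3": din, "dip_mgm3": dip, "poc_mgm3": poc})
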