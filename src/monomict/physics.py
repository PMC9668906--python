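"""Physical submodel of the 1-D lake column.

Density, surface heat budget, underwater light, wind-driven vertical
diffusivity, convective adjustment, and implicit vertical diffusion of any
tracer. The column replaces the 3-D circulation of the original monomictic-
lake problem with a parameterized vertical exchange: wind stirring plus
convective overturn, which are the processes that control stratification and
winter turnover in a deep monomictic basin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np

from . import _kernels as K


@dataclass(frozen=True)
class ColumnGrid:
    """Uniform vertical grid; layer 0 is the surface, depth positive down."""

    n_layers: int = 37
    dz: float = 2.5

    def __post_init__(self):
        if self.n_layers < 3:
            raise ValueError("n_layers must be >= 3")
        if self.dz <= 0:
            raise ValueError("dz must be positive")

    @property
    def mid_depths(self) -> np.ndarray:
        """Layer mid-point depths [m]."""
        return (np.arange(self.n_layers) + 0.5) * self.dz

    @property
    def bottom_depth(self) -> float:
        """Mid-depth of the deepest layer [m]."""
        return (self.n_layers - 0.5) * self.dz


@dataclass
class PhysicsParams:
    """Bulk-flux and mixing coefficients (config block ``physics:``).

    All defaults are package choices for a large temperate monomictic lake;
    every coefficient is exposed so a user can recalibrate.
    """

    albedo: float = 0.07            # shortwave albedo [-]
    sw_surface_fraction: float = 0.45  # non-penetrating shortwave fraction [-]
    extinction: float = 0.35        # background light extinction [1/m]
    extinction_poc: float = 2e-4    # extra extinction per mgC/m³ POC [1/m]
    emissivity: float = 0.97        # water longwave emissivity [-]
    rel_humidity: float = 0.75      # assumed relative humidity [-]
    c_drag: float = 1.3e-3          # momentum transfer coefficient [-]
    c_sensible: float = 1.3e-3      # sensible-heat transfer coefficient [-]
    c_latent: float = 1.3e-3        # latent-heat transfer coefficient [-]
    wind_factor: float = 1.2        # land-station -> over-lake wind ratio [-]
    ck_diffusivity: float = 3.0e4   # K0 = ck * u*³ [s²/m]
    mixing_length: float = 15.0     # e-folding depth of wind K [m]
    k_background: float = 8.0e-6    # floor diffusivity [m²/s]
    n2_damping: float = 3.0e-5      # N² scale of stratification damping [1/s²]
    damping_exponent: float = 1.5   # damping power [-]
    cp_water: float = 4186.0        # specific heat [J/(kg K)]
    lake_area: float = 3.0e8        # column plan area [m²]
    suppress_depth: float = 20.0    # wind-K cutoff depth when mixing is held off [m]

    def to_array(self) -> np.ndarray:
        a = np.empty(K.N_PHYS_PARAMS)
        a[K.P_ALBEDO] = self.albedo
        a[K.P_BETA] = self.sw_surface_fraction
        a[K.P_EXTINCTION] = self.extinction
        a[K.P_EXT_POC] = self.extinction_poc
        a[K.P_EMISS] = self.emissivity
        a[K.P_RH] = self.rel_humidity
        a[K.P_CD] = self.c_drag
        a[K.P_CH] = self.c_sensible
        a[K.P_CE] = self.c_latent
        a[K.P_WIND_FACTOR] = self.wind_factor
        a[K.P_CK] = self.ck_diffusivity
        a[K.P_LMIX] = self.mixing_length
        a[K.P_KBG] = self.k_background
        a[K.P_NDAMP2] = self.n2_damping
        a[K.P_DAMP_EXP] = self.damping_exponent
        a[K.P_CP] = self.cp_water
        a[K.P_AREA] = self.lake_area
        a[K.P_SUPPRESS_DEPTH] = self.suppress_depth
        return a

    @classmethod
    def from_dict(cls, d: dict) -> "PhysicsParams":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown physics keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class HeatFluxBreakdown:
    """Surface heat-budget components [W/m²], positive into the lake."""

    shortwave_abs: float
    shortwave_penetrating: float
    longwave_net: float
    sensible: float
    latent: float

    @property
    def total(self) -> float:
        return (self.shortwave_abs + self.shortwave_penetrating
                + self.longwave_net + self.sensible + self.latent)


def water_density(t):
    """Freshwater density [kg/m³] at temperature ``t`` [°C] (Kell 1975).

    Valid on −0.5..40 °C; has its maximum near 3.98 °C.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < -0.5) or np.any(t_arr > 40.0):
        raise ValueError("temperature outside the valid range [-0.5, 40] °C")
    scalar = t_arr.ndim == 0
    flat = np.atleast_1d(t_arr).astype(float).ravel()
    out = np.empty(flat.shape)
    K.water_density_profile(flat, out)
    if scalar:
        return float(out[0])
    return out.reshape(t_arr.shape)


def surface_heat_flux(meteo_day, t_surface: float,
                      params: PhysicsParams | None = None) -> HeatFluxBreakdown:
    """Bulk surface heat budget for one day's meteorology.

    ``meteo_day`` needs attributes/keys ``air_temp_c``, ``wind_ms``,
    ``cloud_frac``, ``shortwave_wm2`` (land-station wind; the over-lake
    correction is applied internally).
    """
    params = params or PhysicsParams()

    def _get(key):
        if hasattr(meteo_day, key):
            return float(getattr(meteo_day, key))
        return float(meteo_day[key])

    sw_s, sw_pen, lw, sens, lat = K.surface_fluxes(
        _get("air_temp_c"), _get("wind_ms"), _get("cloud_frac"),
        _get("shortwave_wm2"), float(t_surface), params.to_array())
    return HeatFluxBreakdown(sw_s, sw_pen, lw, sens, lat)


def light_profile(shortwave_penetrating: float, grid: ColumnGrid,
                  extinction: float, poc: np.ndarray | None = None,
                  extinction_poc: float = 0.0) -> np.ndarray:
    """Mid-layer irradiance [W/m²], Beer–Lambert with optional POC shading."""
    if extinction <= 0:
        raise ValueError("extinction must be positive")
    poc_arr = np.zeros(grid.n_layers) if poc is None else np.asarray(poc, float)
    pp = PhysicsParams(extinction=extinction,
                       extinction_poc=extinction_poc).to_array()
    absorbed = np.empty(grid.n_layers)
    i_mid = np.empty(grid.n_layers)
    K.light_absorption(float(shortwave_penetrating), poc_arr, grid.dz, pp,
                       absorbed, i_mid)
    return i_mid


def wind_diffusivity(wind_speed_land: float, density: np.ndarray,
                     grid: ColumnGrid,
                     params: PhysicsParams | None = None) -> np.ndarray:
    """Diffusivity [m²/s] at the n−1 interior interfaces.

    Land wind is multiplied by ``wind_factor`` (default 1.2) to approximate
    over-lake wind; the surface value scales with u*³, decays with depth and
    is damped where the density profile is stable. Never below
    ``k_background``.
    """
    if wind_speed_land < 0:
        raise ValueError("wind speed must be >= 0")
    params = params or PhysicsParams()
    rho = np.asarray(density, float)
    k_out = np.empty(grid.n_layers - 1)
    K.wind_diffusivity_profile(float(wind_speed_land), rho, grid.dz,
                               params.to_array(), k_out, False)
    return k_out


def convective_adjustment(temperature: np.ndarray,
                          tracers: np.ndarray | None = None):
    """Homogenize statically unstable layer groups (equal layer volumes).

    Returns ``(temperature, tracers)`` copies with every contiguous density
    inversion mixed to its volume-weighted mean; heat and tracer column sums
    are conserved exactly. ``tracers`` may be ``(m, n)`` or omitted.
    """
    t = np.array(temperature, dtype=float)
    if tracers is None:
        tr = np.zeros((0, t.shape[0]))
    else:
        tr = np.array(tracers, dtype=float)
        if tr.ndim == 1:
            tr = tr[None, :]
    K.convective_adjust(t, tr)
    if tracers is None:
        return t, None
    return t, tr if np.asarray(tracers).ndim > 1 else tr[0]


def diffuse(tracer: np.ndarray, k_iface: np.ndarray, dt: float,
            grid: ColumnGrid, flux_top: float = 0.0,
            flux_bottom: float = 0.0) -> np.ndarray:
    """Implicit (backward Euler) vertical diffusion over one step ``dt`` [s].

    ``k_iface`` holds the n−1 interface diffusivities [m²/s]. Boundary
    fluxes are in tracer-units·m/s, positive into the column, applied as
    explicit sources before the solve. Unconditionally stable; with zero
    boundary fluxes the column sum is conserved to round-off.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    k_arr = np.asarray(k_iface, float)
    if np.any(k_arr < 0):
        raise ValueError("diffusivity must be >= 0")
    c = np.array(tracer, dtype=float)
    c[0] += flux_top * dt / grid.dz
    c[-1] += flux_bottom * dt / grid.dz
    fields = c[None, :].copy()
    K.diffuse_implicit(fields, k_arr, grid.dz, dt)
    return fields[0]


def advance_physics(temperature: np.ndarray, meteo_day, dt: float,
                    grid: ColumnGrid, params: PhysicsParams | None = None,
                    poc: np.ndarray | None = None) -> np.ndarray:
    """One heat-only physics step: surface flux, shortwave absorption,
    wind-driven diffusion, convective adjustment. Returns the new profile.

    The coupled simulator composes the same kernels together with tracer
    transport; this entry point exists for decoupled physics experiments.
    """
    params = params or PhysicsParams()
    pp = params.to_array()
    t = np.array(temperature, dtype=float)
    flux = surface_heat_flux(meteo_day, t[0], params)
    poc_arr = np.zeros(grid.n_layers) if poc is None else np.asarray(poc, float)
    absorbed = np.empty(grid.n_layers)
    i_mid = np.empty(grid.n_layers)
    K.light_absorption(flux.shortwave_penetrating, poc_arr, grid.dz, pp,
                       absorbed, i_mid)
    heat_fac = dt / (K.RHO0 * params.cp_water * grid.dz)
    t[0] += (flux.shortwave_abs + flux.longwave_net + flux.sensible
             + flux.latent) * heat_fac
    t += absorbed * heat_fac
    rho = water_density(t)
    k_if = wind_diffusivity(_meteo_attr(meteo_day, "wind_ms"), rho, grid, params)
    fields = t[None, :].copy()
    K.diffuse_implicit(fields, k_if, grid.dz, dt)
    t = fields[0]
    t, _ = convective_adjustment(t)
    return t


def _meteo_attr(meteo_day, key):
    if hasattr(meteo_day, key):
        return float(getattr(meteo_day, key))
    return float(meteo_day[key])
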