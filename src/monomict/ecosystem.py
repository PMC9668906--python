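"""Pelagic ecosystem submodel: biochemical source/sink terms for the six
state variables (phytoplankton, zooplankton, DIN, DIP, DO, POC), plus
reaeration, particle sinking, and a single-pool sediment exchange.

The functional forms are a conventional NPZD-style closure: Michaelis–Menten
nutrient limitation with a Liebig minimum, a saturating light response, Q10
temperature scaling, linear mortality, Ivlev grazing, first-order (implicit-
bacteria) decomposition, and fixed Redfield stoichiometry. A diagnostic DIC
pool absorbs respired / photosynthesized carbon so that elemental budgets
close exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np

from . import _kernels as K

#: mass stoichiometric ratios (Redfield C:N:P = 106:16:1 molar)
N_TO_C = 16 * 14.007 / (106 * 12.011)   # gN per gC
P_TO_C = 30.974 / (106 * 12.011)        # gP per gC
O2_TO_C = 32.0 / 12.011                 # gO2 per gC respired/fixed


@dataclass
class EcoParams:
    """Biochemical rate constants (config block ``ecology:``).

    All rates are per day at the 20 °C reference temperature unless noted;
    the original lake application inherited its parameter set from
    predecessor models, so these are literature-plausible package defaults,
    each exposed for recalibration.
    """

    mu_max: float = 2.0             # max phyto growth [1/day]
    k_light: float = 25.0           # light half-saturation [W/m²]
    k_din: float = 10.0             # DIN half-saturation [µgN/L]
    k_dip: float = 2.0              # DIP half-saturation [µgP/L]
    resp_phy: float = 0.05          # phyto respiration [1/day]
    mort_phy: float = 0.03          # phyto mortality [1/day]
    graze_max: float = 0.3          # max specific grazing [1/day]
    ivlev: float = 0.02             # Ivlev coefficient [m³/mgC]
    graze_threshold: float = 5.0    # grazing threshold [mgC/m³]
    assimilation: float = 0.7       # zoo assimilation efficiency [-]
    resp_zoo: float = 0.05          # zoo respiration/excretion [1/day]
    mort_zoo: float = 0.02          # zoo mortality [1/day]
    decomposition: float = 0.015    # water POC decomposition [1/day]
    w_sink_phy: float = 0.3         # phyto sinking [m/day]
    w_sink_poc: float = 3.0         # POC sinking [m/day]
    k_reaeration: float = 1.0       # reaeration piston velocity [m/day]
    sed_decay: float = 0.0012       # sediment C decay [1/day]
    sed_p_enhance: float = 3.0      # low-DO P-release amplitude [-]
    sed_kdo: float = 2.0            # DO half-saturation of enhancement [mg/L]
    q10: float = 2.0                # Q10 of temperature-dependent rates [-]
    kdo_water: float = 0.5          # DO half-sat of water decomposition [mg/L]
    do_cap: float = 1.2             # supersaturation cap (× saturation) [-]
    excrete_direct: bool = True     # zoo respiration excretes to DIN/DIP

    def __post_init__(self):
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if isinstance(v, bool):
                continue
            if v < 0:
                raise ValueError(f"{f.name} must be >= 0")
        if not 0 <= self.assimilation <= 1:
            raise ValueError("assimilation must be in [0, 1]")

    def to_array(self) -> np.ndarray:
        a = np.empty(K.N_ECO_PARAMS)
        a[K.E_MU_MAX] = self.mu_max
        a[K.E_KI] = self.k_light
        a[K.E_KN] = self.k_din
        a[K.E_KP] = self.k_dip
        a[K.E_RESP_PHY] = self.resp_phy
        a[K.E_MORT_PHY] = self.mort_phy
        a[K.E_GMAX] = self.graze_max
        a[K.E_IVLEV] = self.ivlev
        a[K.E_GTHRESH] = self.graze_threshold
        a[K.E_ASSIM] = self.assimilation
        a[K.E_RESP_ZOO] = self.resp_zoo
        a[K.E_MORT_ZOO] = self.mort_zoo
        a[K.E_DECOMP] = self.decomposition
        a[K.E_W_PHY] = self.w_sink_phy
        a[K.E_W_POC] = self.w_sink_poc
        a[K.E_K_REA] = self.k_reaeration
        a[K.E_SED_DECAY] = self.sed_decay
        a[K.E_SED_A] = self.sed_p_enhance
        a[K.E_SED_KDO] = self.sed_kdo
        a[K.E_NC] = N_TO_C
        a[K.E_PC] = P_TO_C
        a[K.E_OC] = O2_TO_C
        a[K.E_Q10] = self.q10
        a[K.E_KDO_W] = self.kdo_water
        a[K.E_DO_CAP] = self.do_cap
        a[K.E_EXCRETE_DIRECT] = 1.0 if self.excrete_direct else 0.0
        return a

    @classmethod
    def from_dict(cls, d: dict) -> "EcoParams":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown ecology keys: {sorted(unknown)}")
        return cls(**d)

    def describe(self) -> list[tuple[str, float, str]]:
        """(name, default, unit/comment) for every parameter."""
        units = {
            "mu_max": "1/day at 20 °C", "k_light": "W/m²",
            "k_din": "µgN/L", "k_dip": "µgP/L", "resp_phy": "1/day",
            "mort_phy": "1/day", "graze_max": "1/day", "ivlev": "m³/mgC",
            "graze_threshold": "mgC/m³", "assimilation": "-",
            "resp_zoo": "1/day", "mort_zoo": "1/day",
            "decomposition": "1/day", "w_sink_phy": "m/day",
            "w_sink_poc": "m/day", "k_reaeration": "m/day",
            "sed_decay": "1/day", "sed_p_enhance": "-", "sed_kdo": "mg/L",
            "q10": "-", "kdo_water": "mg/L", "do_cap": "× saturation",
            "excrete_direct": "bool",
        }
        return [(f.name, getattr(self, f.name), units[f.name])
                for f in dc_fields(self)]


def growth_limitation(irradiance, din, dip, temperature,
                      params: EcoParams | None = None) -> dict:
    """Phytoplankton limitation factors.

    f_N and f_P are Michaelis–Menten, f_light saturating, f_T the Q10 factor
    (may exceed 1 above 20 °C); ``f_total = f_light · min(f_N, f_P) · f_T``
    (Liebig's minimum for nutrients).
    """
    p = params or EcoParams()
    if np.any(np.asarray([irradiance, din, dip]) < 0):
        raise ValueError("irradiance and nutrient concentrations must be >= 0")
    f_light = irradiance / (p.k_light + irradiance)
    f_n = din / (p.k_din + din)
    f_p = dip / (p.k_dip + dip)
    f_t = p.q10 ** ((temperature - 20.0) / 10.0)
    return {"f_light": f_light, "f_N": f_n, "f_P": f_p, "f_T": f_t,
            "f_total": f_light * min(f_n, f_p) * f_t}


def ecosystem_tendencies(state_layer: dict, env_layer: dict,
                         params: EcoParams | None = None) -> dict:
    """Instantaneous biochemical tendencies for one layer [per day].

    ``state_layer`` keys: phy, zoo, poc, din, dip, do (model units);
    ``env_layer`` keys: irradiance [W/m²], temperature [°C].
    Every C/N/P/O flux appears with opposite sign in exactly two budgets (or
    a boundary), so the Redfield-weighted totals close identically; the
    returned ``dic`` tendency absorbs net community production.
    """
    p = params or EcoParams()
    order = ("phy", "zoo", "poc", "din", "dip", "do")
    vals = [float(state_layer[k]) for k in order]
    if any(v < 0 for v in vals):
        raise ValueError("state concentrations must be >= 0")
    tr = np.zeros((K.N_TRACERS, 1))
    tr[:6, 0] = vals
    temp = np.array([float(env_layer["temperature"])])
    i_mid = np.array([float(env_layer["irradiance"])])
    fl = np.empty((1, 7))
    K.eco_fluxes(temp, tr, i_mid, p.to_array(), fl)
    growth, rp, mp, gr, rz, mz, dec = fl[0]
    remin = rp + rz + dec
    return {
        "phy": growth - rp - mp - gr,
        "zoo": p.assimilation * gr - rz - mz,
        "poc": mp + mz + (1 - p.assimilation) * gr - dec,
        "din": N_TO_C * (remin - growth),
        "dip": P_TO_C * (remin - growth),
        "do": O2_TO_C * (growth - remin) / 1000.0,
        "dic": remin - growth,
    }


def do_saturation(t):
    """Freshwater dissolved-oxygen saturation [mg/L] (Benson–Krause)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > 40):
        raise ValueError("temperature outside [0, 40] °C")
    tk = t_arr + 273.15
    out = np.exp(-139.34411 + 1.575701e5 / tk - 6.642308e7 / tk ** 2
                 + 1.243800e10 / tk ** 3 - 8.621949e11 / tk ** 4)
    return float(out) if out.ndim == 0 else out


def reaeration_flux(do_surface: float, t_surface: float, k_rea: float,
                    dz: float = 2.5) -> float:
    """Surface-layer DO tendency from air–water exchange [mg/(L·day)].

    Linear relaxation toward saturation with piston velocity ``k_rea``
    [m/day] spread over the surface layer thickness; sign-symmetric about
    saturation (degassing when supersaturated).
    """
    if k_rea < 0:
        raise ValueError("k_rea must be >= 0")
    return k_rea * (do_saturation(t_surface) - do_surface) / dz


def sinking(profile: np.ndarray, w_sink: float, dt: float,
            grid) -> tuple[np.ndarray, float]:
    """First-order upwind downward transport over ``dt`` [s].

    Returns ``(new_profile, flux_to_sediment)`` where the flux is the mass
    per unit area (concentration-units × m) leaving the bottom layer.
    Requires the CFL bound ``w_sink·dt <= dz``.
    """
    if w_sink < 0:
        raise ValueError("w_sink must be >= 0")
    w_dt = w_sink * dt / 86400.0
    if w_dt > grid.dz:
        raise ValueError(
            f"sinking CFL violated: w_sink*dt = {w_dt:.3g} m > dz = {grid.dz} m")
    c = np.array(profile, dtype=float)
    export = K.sinking_step(c, w_dt, grid.dz)
    return c, export


def sediment_exchange(sed_pools: np.ndarray, do_bottom: float,
                      t_bottom: float, params: EcoParams | None = None,
                      dz: float = 2.5, dt_days: float = 1.0) -> dict:
    """One sediment-exchange step; mutates ``sed_pools`` (C, N, P) [g/m²].

    Sediment carbon decays at a Q10-scaled first-order rate; the oxygen
    demand drawn from the bottom layer is capped so DO stays nonnegative
    (the unmet remainder is the anaerobic pathway); N is released in pool
    stoichiometry and P with the low-DO enhancement
    ``1 + a·K_DO/(K_DO + DO)``.
    """
    p = params or EcoParams()
    if np.any(np.asarray(sed_pools) < 0):
        raise ValueError("sediment pools must be >= 0")
    sed = np.asarray(sed_pools, dtype=float)
    d_do, d_din, d_dip, d_dic, o2_app, o2_un = K.sediment_step(
        float(t_bottom), float(do_bottom), sed, p.to_array(), dz, dt_days)
    return {"d_do": d_do, "d_din": d_din, "d_dip": d_dip, "d_dic": d_dic,
            "o2_demand": o2_app, "o2_unmet": o2_un, "pools": sed}
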