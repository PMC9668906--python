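"""Numba-compiled numerical kernels shared by the physics, ecosystem and
simulator modules.

There is exactly one implementation of every numerical operation: the public
module functions (``physics.diffuse``, ``physics.convective_adjustment``,
``ecosystem.sinking`` ...) are thin wrappers over the kernels in this file,
and the multi-year run loop (`simulate_days`) composes the same kernels.

Conventions
-----------
* Layer 0 is the surface; depth increases with index; layers share one ``dz``.
* Temperature is °C. Tracers are stacked in a ``(7, n_layers)`` array in the
  order PHY, ZOO, POC (mgC/m³), DIN (µgN/L = mgN/m³), DIP (µgP/L = mgP/m³),
  DO (mg/L = gO₂/m³), DIC (mgC/m³, diagnostic — may be negative).
* Sediment pools are ``(3,)``: organic C (gC/m²), N (gN/m²), P (gP/m²).
* Parameter vectors are flat float64 arrays addressed by the ``P_*`` / ``E_*``
  index constants below; the config dataclasses build them.
"""

import math

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# tracer indices
I_PHY, I_ZOO, I_POC, I_DIN, I_DIP, I_DO, I_DIC = 0, 1, 2, 3, 4, 5, 6
N_TRACERS = 7

# physics parameter indices
P_ALBEDO = 0        # shortwave albedo [-]
P_BETA = 1          # fraction of net shortwave absorbed in the surface layer
P_EXTINCTION = 2    # background light extinction [1/m]
P_EXT_POC = 3       # extinction per unit POC [1/m per mgC/m³]
P_EMISS = 4         # water longwave emissivity [-]
P_RH = 5            # relative humidity used in bulk fluxes [-]
P_CD = 6            # drag coefficient [-]
P_CH = 7            # sensible-heat transfer coefficient [-]
P_CE = 8            # latent-heat transfer coefficient [-]
P_WIND_FACTOR = 9   # land -> lake wind correction (1.2)
P_CK = 10           # wind diffusivity scale: K0 = CK * u*^3 [s²/m]
P_LMIX = 11         # e-folding depth of wind-driven K [m]
P_KBG = 12          # background diffusivity [m²/s]
P_NDAMP2 = 13       # N² scale for stratification damping [1/s²]
P_DAMP_EXP = 14     # damping exponent [-]
P_CP = 15           # specific heat of water [J/(kg K)]
P_AREA = 16         # lake (column) area [m²]
P_SUPPRESS_DEPTH = 17  # depth below which wind K is zeroed when mixing is suppressed [m]
N_PHYS_PARAMS = 18

# ecology parameter indices
E_MU_MAX = 0        # max phytoplankton growth [1/day at 20 °C]
E_KI = 1            # light half-saturation [W/m²]
E_KN = 2            # DIN half-saturation [µgN/L]
E_KP = 3            # DIP half-saturation [µgP/L]
E_RESP_PHY = 4      # phyto respiration [1/day at 20 °C]
E_MORT_PHY = 5      # phyto mortality [1/day]
E_GMAX = 6          # max grazing [1/day at 20 °C]
E_IVLEV = 7         # Ivlev grazing coefficient [m³/mgC]
E_GTHRESH = 8       # grazing threshold [mgC/m³]
E_ASSIM = 9         # zooplankton assimilation efficiency [-]
E_RESP_ZOO = 10     # zoo respiration/excretion [1/day at 20 °C]
E_MORT_ZOO = 11     # zoo mortality [1/day]
E_DECOMP = 12       # POC decomposition [1/day at 20 °C]
E_W_PHY = 13        # phyto sinking speed [m/day]
E_W_POC = 14        # POC sinking speed [m/day]
E_K_REA = 15        # reaeration piston velocity [m/day]
E_SED_DECAY = 16    # sediment C decay [1/day at 20 °C]
E_SED_A = 17        # low-DO P-release enhancement amplitude [-]
E_SED_KDO = 18      # DO half-saturation of the enhancement [mg/L]
E_NC = 19           # N:C mass ratio (Redfield)
E_PC = 20           # P:C mass ratio (Redfield)
E_OC = 21           # O2:C mass ratio (32/12)
E_Q10 = 22          # Q10 for all temperature-dependent rates
E_KDO_W = 23        # DO half-saturation of water-column decomposition [mg/L]
E_DO_CAP = 24       # supersaturation cap (× saturation)
E_EXCRETE_DIRECT = 25  # 1: zoo respiration excretes to DIN/DIP; 0: via POC
N_ECO_PARAMS = 26

# ledger column indices (per-day accumulated boundary fluxes)
L_HEAT_SURF = 0     # surface heat input [J/m²]
L_HEAT_RIV = 1      # net river heat input [J/m²]
L_C_RIV = 2         # net river C input [mgC/m²]
L_N_RIV = 3         # net river N input [mgN/m²]
L_P_RIV = 4         # net river P input [mgP/m²]
L_O2_AIR = 5        # reaeration O2 input [g/m²]
L_O2_SED = 6        # sediment O2 demand (negative = loss) [g/m²]
L_O2_VENT = 7       # supersaturation venting (negative = loss) [g/m²]
L_O2_RIV = 8        # net river O2 input [g/m²]
L_O2_ANAER = 9      # unmet (anaerobic) sediment O2 demand [g/m²]
L_DIC_RIV = 10      # net river DIC input (outflow only; rivers carry none) [mgC/m²]
N_LEDGER = 11

GRAV = 9.81
RHO_AIR = 1.2       # kg/m³
CP_AIR = 1005.0     # J/(kg K)
LV = 2.5e6          # J/kg latent heat of vaporisation
SIGMA_SB = 5.670374419e-8
P_ATM = 1013.25     # hPa
RHO0 = 1000.0       # reference density for heat-content bookkeeping


# ---------------------------------------------------------------------------
# equation of state (Kell 1975 rational polynomial, salinity 0)

@njit(cache=True)
def water_density_scalar(t):
    num = (999.83952 + 16.945176 * t - 7.9870401e-3 * t * t
           - 46.170461e-6 * t ** 3 + 105.56302e-9 * t ** 4
           - 280.54253e-12 * t ** 5)
    return num / (1.0 + 16.879850e-3 * t)


@njit(cache=True)
def water_density_profile(temp, out):
    for i in range(temp.shape[0]):
        out[i] = water_density_scalar(temp[i])


# ---------------------------------------------------------------------------
# dissolved-oxygen saturation (Benson & Krause, freshwater)

@njit(cache=True)
def do_saturation_scalar(t):
    tk = t + 273.15
    return math.exp(-139.34411 + 1.575701e5 / tk - 6.642308e7 / tk ** 2
                    + 1.243800e10 / tk ** 3 - 8.621949e11 / tk ** 4)


# ---------------------------------------------------------------------------
# tridiagonal solver (Thomas algorithm, multiple right-hand sides)

@njit(cache=True)
def thomas_solve(lower, diag, upper, rhs):
    """Solve tridiagonal systems in place; ``rhs`` is (n, m)."""
    n, m = rhs.shape
    cp = np.empty(n)
    cp[0] = upper[0] / diag[0]
    for j in range(m):
        rhs[0, j] = rhs[0, j] / diag[0]
    for i in range(1, n):
        denom = diag[i] - lower[i] * cp[i - 1]
        cp[i] = upper[i] / denom
        for j in range(m):
            rhs[i, j] = (rhs[i, j] - lower[i] * rhs[i - 1, j]) / denom
    for i in range(n - 2, -1, -1):
        for j in range(m):
            rhs[i, j] -= cp[i] * rhs[i + 1, j]


@njit(cache=True)
def diffuse_implicit(fields, k_iface, dz, dt):
    """Backward-Euler vertical diffusion of ``fields`` (m, n) in place.

    ``k_iface`` holds diffusivity at the n-1 interior interfaces; the top and
    bottom boundaries are no-flux. Column sums are conserved exactly (up to
    solver round-off).
    """
    m, n = fields.shape
    lower = np.empty(n)
    diag = np.empty(n)
    upper = np.empty(n)
    r = dt / (dz * dz)
    lower[0] = 0.0
    upper[n - 1] = 0.0
    for i in range(n):
        kl = k_iface[i - 1] if i > 0 else 0.0
        ku = k_iface[i] if i < n - 1 else 0.0
        if i > 0:
            lower[i] = -r * kl
        if i < n - 1:
            upper[i] = -r * ku
        diag[i] = 1.0 + r * (kl + ku)
    rhs = np.empty((n, m))
    for i in range(n):
        for j in range(m):
            rhs[i, j] = fields[j, i]
    thomas_solve(lower, diag, upper, rhs)
    for i in range(n):
        for j in range(m):
            fields[j, i] = rhs[i, j]


# ---------------------------------------------------------------------------
# convective adjustment (pool-adjacent-violators on density, equal volumes)

@njit(cache=True)
def convective_adjust(temp, tracers):
    """Homogenize statically unstable contiguous layer groups in place.

    Merges adjacent groups while the upper group's density (of its mean
    temperature) exceeds the lower group's, conserving layer sums of
    temperature and every tracer exactly.
    """
    n = temp.shape[0]
    m = tracers.shape[0]
    g_t = np.empty(n)
    g_tr = np.empty((m, n))
    g_cnt = np.empty(n, np.int64)
    ng = 0
    for i in range(n):
        g_t[ng] = temp[i]
        g_cnt[ng] = 1
        for k in range(m):
            g_tr[k, ng] = tracers[k, i]
        ng += 1
        while ng > 1:
            rho_up = water_density_scalar(g_t[ng - 2] / g_cnt[ng - 2])
            rho_lo = water_density_scalar(g_t[ng - 1] / g_cnt[ng - 1])
            if rho_up > rho_lo + 1e-12:
                g_t[ng - 2] += g_t[ng - 1]
                g_cnt[ng - 2] += g_cnt[ng - 1]
                for k in range(m):
                    g_tr[k, ng - 2] += g_tr[k, ng - 1]
                ng -= 1
            else:
                break
    pos = 0
    for g in range(ng):
        tm = g_t[g] / g_cnt[g]
        for _ in range(g_cnt[g]):
            temp[pos] = tm
            for k in range(m):
                tracers[k, pos] = g_tr[k, g] / g_cnt[g]
            pos += 1


# ---------------------------------------------------------------------------
# surface heat fluxes (bulk formulas; positive = into the lake)

@njit(cache=True)
def vapor_pressure(t):
    """Saturation vapor pressure [hPa] (Magnus)."""
    return 6.1094 * math.exp(17.625 * t / (t + 243.04))


@njit(cache=True)
def surface_fluxes(air_t, wind_land, cloud, shortwave, t_surf, pp):
    """Return (sw_surface, sw_penetrating, longwave_net, sensible, latent).

    ``sw_surface`` is the part of net shortwave deposited in layer 0;
    ``sw_penetrating`` enters the light profile below the surface layer.
    """
    u = pp[P_WIND_FACTOR] * wind_land
    sw_net = (1.0 - pp[P_ALBEDO]) * shortwave
    sw_surf = pp[P_BETA] * sw_net
    sw_pen = sw_net - sw_surf
    ta_k = air_t + 273.15
    ts_k = t_surf + 273.15
    e_a = pp[P_RH] * vapor_pressure(air_t)
    # Brutsaert clear-sky emissivity with a quadratic cloud correction
    eps_a = 1.24 * (e_a / ta_k) ** (1.0 / 7.0) * (1.0 + 0.22 * cloud * cloud)
    if eps_a > 1.0:
        eps_a = 1.0
    lw = pp[P_EMISS] * SIGMA_SB * (eps_a * ta_k ** 4 - ts_k ** 4)
    sensible = RHO_AIR * CP_AIR * pp[P_CH] * u * (air_t - t_surf)
    q_a = 0.622 * e_a / (P_ATM - 0.378 * e_a)
    e_s = vapor_pressure(t_surf)
    q_s = 0.622 * e_s / (P_ATM - 0.378 * e_s)
    latent = RHO_AIR * LV * pp[P_CE] * u * (q_a - q_s)
    return sw_surf, sw_pen, lw, sensible, latent


@njit(cache=True)
def light_absorption(sw_pen, poc, dz, pp, absorbed, i_mid):
    """Absorbed shortwave per layer [W/m²] and mid-layer irradiance [W/m²].

    Extinction is background + POC shading; radiation reaching the bed is
    absorbed in the bottom layer so the column heat budget closes.
    """
    n = poc.shape[0]
    inten = sw_pen
    for i in range(n):
        k = pp[P_EXTINCTION] + pp[P_EXT_POC] * poc[i]
        i_mid[i] = inten * math.exp(-k * dz * 0.5)
        nxt = inten * math.exp(-k * dz)
        absorbed[i] = inten - nxt
        inten = nxt
    absorbed[n - 1] += inten  # bed absorption


@njit(cache=True)
def wind_diffusivity_profile(wind_land, rho, dz, pp, k_out, suppress):
    """Vertical diffusivity at the n-1 interior interfaces [m²/s].

    Surface value scales with the cube of the waterside friction velocity,
    decays exponentially with depth, and is damped where the density
    gradient is stable (Richardson-style N² damping). Never below KBG.
    """
    n = rho.shape[0]
    u = pp[P_WIND_FACTOR] * wind_land
    ustar = math.sqrt(RHO_AIR * pp[P_CD] * u * u / RHO0)
    k0 = pp[P_CK] * ustar ** 3
    for i in range(n - 1):
        z = (i + 1) * dz
        drho = rho[i + 1] - rho[i]
        n2 = GRAV / RHO0 * drho / dz
        if n2 < 0.0:
            n2 = 0.0
        damp = (1.0 + n2 / pp[P_NDAMP2]) ** pp[P_DAMP_EXP]
        kw = k0 * math.exp(-z / pp[P_LMIX]) / damp
        if suppress and z >= pp[P_SUPPRESS_DEPTH]:
            kw = 0.0
        k_out[i] = pp[P_KBG] + kw


# ---------------------------------------------------------------------------
# sinking (first-order upwind), returns exported mass per m² of column

@njit(cache=True)
def sinking_step(c, w_dt, dz):
    """Downward upwind transport by ``w_dt = w*dt`` [m]; returns the mass
    (concentration × m) leaving the bottom layer. Requires w_dt <= dz."""
    n = c.shape[0]
    f = w_dt / dz
    export = c[n - 1] * w_dt
    for i in range(n - 1, 0, -1):
        c[i] += f * (c[i - 1] - c[i])
    c[0] -= f * c[0]
    return export


# ---------------------------------------------------------------------------
# ecology

@njit(cache=True)
def eco_fluxes(temp, tracers, i_mid, ep, out):
    """Gross biochemical fluxes per layer, all in mgC/(m³ day).

    Columns of ``out`` (n, 7): growth, phyto respiration, phyto mortality,
    grazing, zoo respiration, zoo mortality, POC decomposition. Water-column
    decomposition is DO-limited (Monod); no stock capping here — the
    integrator applies availability caps.
    """
    n = temp.shape[0]
    for i in range(n):
        ft = ep[E_Q10] ** ((temp[i] - 20.0) / 10.0)
        phy = tracers[I_PHY, i]
        zoo = tracers[I_ZOO, i]
        poc = tracers[I_POC, i]
        din = tracers[I_DIN, i]
        dip = tracers[I_DIP, i]
        do = tracers[I_DO, i]
        f_i = i_mid[i] / (ep[E_KI] + i_mid[i])
        f_n = din / (ep[E_KN] + din)
        f_p = dip / (ep[E_KP] + dip)
        f_nut = f_n if f_n < f_p else f_p
        out[i, 0] = ep[E_MU_MAX] * ft * f_i * f_nut * phy
        out[i, 1] = ep[E_RESP_PHY] * ft * phy
        out[i, 2] = ep[E_MORT_PHY] * phy
        excess = phy - ep[E_GTHRESH]
        if excess < 0.0:
            excess = 0.0
        out[i, 3] = ep[E_GMAX] * ft * (1.0 - math.exp(-ep[E_IVLEV] * excess)) * zoo
        rz = ep[E_RESP_ZOO] * ft * zoo
        mz = ep[E_MORT_ZOO] * zoo
        if ep[E_EXCRETE_DIRECT] < 0.5:
            mz += rz
            rz = 0.0
        out[i, 4] = rz
        out[i, 5] = mz
        out[i, 6] = ep[E_DECOMP] * ft * poc * do / (ep[E_KDO_W] + do)


@njit(cache=True)
def eco_apply(temp, tracers, i_mid, ep, dt_days):
    """Capped-sink forward-Euler biochemical update (in place).

    Each pool's outgoing fluxes are jointly scaled so no pool is driven
    below zero within the sub-step; every flux keeps its paired source and
    destination, so elemental closure is exact by construction.
    """
    n = temp.shape[0]
    fl = np.empty((n, 7))
    eco_fluxes(temp, tracers, i_mid, ep, fl)
    tiny = 1e-300
    for i in range(n):
        growth, rp, mp, gr, rz, mz, dec = (fl[i, 0], fl[i, 1], fl[i, 2],
                                           fl[i, 3], fl[i, 4], fl[i, 5],
                                           fl[i, 6])
        phy = tracers[I_PHY, i]
        zoo = tracers[I_ZOO, i]
        poc = tracers[I_POC, i]
        din = tracers[I_DIN, i]
        dip = tracers[I_DIP, i]
        do = tracers[I_DO, i]
        # source-pool caps
        tot = (rp + mp + gr) * dt_days
        if tot > phy:
            s = phy / (tot + tiny)
            rp *= s
            mp *= s
            gr *= s
        tot = (rz + mz) * dt_days
        if tot > zoo:
            s = zoo / (tot + tiny)
            rz *= s
            mz *= s
        if dec * dt_days > poc:
            dec = poc / dt_days
        # nutrient caps on growth
        if growth * ep[E_NC] * dt_days > din + (rp + rz + dec) * ep[E_NC] * dt_days:
            avail = din / (ep[E_NC] * dt_days + tiny) + rp + rz + dec
            if growth > avail:
                growth = avail
        if growth * ep[E_PC] * dt_days > dip + (rp + rz + dec) * ep[E_PC] * dt_days:
            avail = dip / (ep[E_PC] * dt_days + tiny) + rp + rz + dec
            if growth > avail:
                growth = avail
        # DO cap on oxidative sinks (respiration + decomposition jointly)
        o2_sink = (rp + rz + dec) * ep[E_OC] / 1000.0
        o2_src = growth * ep[E_OC] / 1000.0
        if (o2_sink - o2_src) * dt_days > do:
            scale = (do / dt_days + o2_src) / (o2_sink + tiny)
            if scale < 1.0:
                rp *= scale
                rz *= scale
                dec *= scale
        tracers[I_PHY, i] = phy + dt_days * (growth - rp - mp - gr)
        tracers[I_ZOO, i] = zoo + dt_days * (ep[E_ASSIM] * gr - rz - mz)
        tracers[I_POC, i] = poc + dt_days * (mp + mz + (1.0 - ep[E_ASSIM]) * gr - dec)
        remin = rp + rz + dec
        tracers[I_DIN, i] = din + dt_days * ep[E_NC] * (remin - growth)
        tracers[I_DIP, i] = dip + dt_days * ep[E_PC] * (remin - growth)
        tracers[I_DO, i] = do + dt_days * ep[E_OC] * (growth - remin) / 1000.0
        tracers[I_DIC, i] = tracers[I_DIC, i] + dt_days * (remin - growth)
        # round-off guard
        for k in range(6):
            if tracers[k, i] < 0.0:
                tracers[k, i] = 0.0
        if tracers[I_DO, i] < 0.0:
            tracers[I_DO, i] = 0.0


@njit(cache=True)
def sediment_step(t_bot, do_bot, sed, ep, dz, dt_days):
    """One sediment-exchange sub-step.

    Returns (d_DO [mg/L], d_DIN [µgN/L], d_DIP [µgP/L], d_DIC [mgC/m³],
    o2_applied [g/m²], o2_unmet [g/m²]) for the bottom layer; mutates ``sed``.
    Decay proceeds regardless of DO (anaerobic pathway); the oxygen demand
    actually drawn from the bottom layer is capped so DO stays >= 0, and the
    unmet remainder is reported for the oxygen ledger.
    """
    if sed[0] <= 0.0:
        return 0.0, 0.0, 0.0, 0.0, 0.0, 0.0
    ft = ep[E_Q10] ** ((t_bot - 20.0) / 10.0)
    decay = ep[E_SED_DECAY] * ft * sed[0]          # gC/m²/day
    if decay * dt_days > sed[0]:
        decay = sed[0] / dt_days
    n_rel = decay * (sed[1] / sed[0])              # gN/m²/day
    enh = 1.0 + ep[E_SED_A] * ep[E_SED_KDO] / (ep[E_SED_KDO] + do_bot)
    p_rel = decay * (sed[2] / sed[0]) * enh        # gP/m²/day
    if n_rel * dt_days > sed[1]:
        n_rel = sed[1] / dt_days
    if p_rel * dt_days > sed[2]:
        p_rel = sed[2] / dt_days
    demand = decay * ep[E_OC] * dt_days            # gO2/m² this sub-step
    avail = do_bot * dz
    applied = demand if demand < avail else avail
    unmet = demand - applied
    sed[0] -= decay * dt_days
    sed[1] -= n_rel * dt_days
    sed[2] -= p_rel * dt_days
    d_do = -applied / dz
    d_din = n_rel * dt_days * 1000.0 / dz
    d_dip = p_rel * dt_days * 1000.0 / dz
    d_dic = decay * dt_days * 1000.0 / dz
    return d_do, d_din, d_dip, d_dic, applied, unmet


# ---------------------------------------------------------------------------
# the coupled run loop

@njit(cache=True)
def simulate_days(temp, tracers, sed, forcing, river, pp, ep, dz, dt,
                  n_sub, eco_on, suppress_mixing,
                  arch_t, arch_tr, arch_sed, ledger):
    """March the column through ``forcing.shape[0]`` days (in place).

    forcing: (nd, 5) air_t, wind, cloud, precip, shortwave (daily values).
    river:   (nd, 5) flow [m³/day], temp [°C], DIN, DIP [mg/m³], POC [mgC/m³].
    Archives daily means of temperature and tracers, end-of-day sediment
    pools, and per-day boundary-flux ledgers.

    Splitting per sub-step: surface heat + shortwave absorption → implicit
    vertical diffusion of heat and all tracers (shared K) → convective
    adjustment (heat + tracers) → sinking → biochemical reactions →
    reaeration, sediment exchange, supersaturation venting → river
    source/sink on the surface layer.
    """
    nd = forcing.shape[0]
    n = temp.shape[0]
    dt_days = dt / 86400.0
    rho = np.empty(n)
    k_if = np.empty(n - 1)
    absorbed = np.empty(n)
    i_mid = np.empty(n)
    fields = np.empty((1 + N_TRACERS, n))
    heat_fac = dt / (RHO0 * pp[P_CP] * dz)
    area = pp[P_AREA]
    for d in range(nd):
        air_t = forcing[d, 0]
        wind = forcing[d, 1]
        cloud = forcing[d, 2]
        sw = forcing[d, 4]
        q_riv = river[d, 0]
        t_riv = river[d, 1]
        r_frac = q_riv * dt_days / (area * dz)
        do_riv = do_saturation_scalar(t_riv)
        for k in range(n):
            arch_t[d, k] = 0.0
            for j in range(N_TRACERS):
                arch_tr[j, d, k] = 0.0
        for s in range(n_sub):
            # --- surface heat + light
            sw_s, sw_pen, lw, sens, lat = surface_fluxes(
                air_t, wind, cloud, sw, temp[0], pp)
            light_absorption(sw_pen, tracers[I_POC], dz, pp, absorbed, i_mid)
            q_surf = sw_s + lw + sens + lat
            temp[0] += q_surf * heat_fac
            for i in range(n):
                temp[i] += absorbed[i] * heat_fac
            ledger[d, L_HEAT_SURF] += (q_surf + sw_pen) * dt
            # --- vertical mixing
            water_density_profile(temp, rho)
            wind_diffusivity_profile(wind, rho, dz, pp, k_if, suppress_mixing)
            for i in range(n):
                fields[0, i] = temp[i]
                for j in range(N_TRACERS):
                    fields[1 + j, i] = tracers[j, i]
            diffuse_implicit(fields, k_if, dz, dt)
            for i in range(n):
                temp[i] = fields[0, i]
                for j in range(N_TRACERS):
                    tracers[j, i] = fields[1 + j, i]
            if not suppress_mixing:
                convective_adjust(temp, tracers)
            if eco_on:
                # --- sinking
                exp_phy = sinking_step(tracers[I_PHY], ep[E_W_PHY] * dt_days, dz)
                exp_poc = sinking_step(tracers[I_POC], ep[E_W_POC] * dt_days, dz)
                exp_c = (exp_phy + exp_poc) / 1000.0   # gC/m²
                sed[0] += exp_c
                sed[1] += exp_c * ep[E_NC]
                sed[2] += exp_c * ep[E_PC]
                # --- reactions
                eco_apply(temp, tracers, i_mid, ep, dt_days)
                # --- reaeration
                sat0 = do_saturation_scalar(temp[0])
                d_do = ep[E_K_REA] * dt_days * (sat0 - tracers[I_DO, 0]) / dz
                tracers[I_DO, 0] += d_do
                ledger[d, L_O2_AIR] += d_do * dz
                # --- sediment exchange
                d_do, d_din, d_dip, d_dic, o2_app, o2_un = sediment_step(
                    temp[n - 1], tracers[I_DO, n - 1], sed, ep, dz, dt_days)
                tracers[I_DO, n - 1] += d_do
                tracers[I_DIN, n - 1] += d_din
                tracers[I_DIP, n - 1] += d_dip
                tracers[I_DIC, n - 1] += d_dic
                ledger[d, L_O2_SED] -= o2_app
                ledger[d, L_O2_ANAER] += o2_un
                # --- supersaturation venting
                for i in range(n):
                    cap = ep[E_DO_CAP] * do_saturation_scalar(temp[i])
                    if tracers[I_DO, i] > cap:
                        ledger[d, L_O2_VENT] -= (tracers[I_DO, i] - cap) * dz
                        tracers[I_DO, i] = cap
            # --- river exchange (inflow to / outflow from the surface layer)
            if r_frac > 0.0:
                ledger[d, L_HEAT_RIV] += (r_frac * (t_riv - temp[0])
                                          * RHO0 * pp[P_CP] * dz)
                temp[0] += r_frac * (t_riv - temp[0])
                c_in = river[d, 4]
                din_in = river[d, 2]
                dip_in = river[d, 3]
                ledger[d, L_C_RIV] += r_frac * dz * (
                    c_in - tracers[I_POC, 0] - tracers[I_PHY, 0]
                    - tracers[I_ZOO, 0] - tracers[I_DIC, 0])
                ledger[d, L_N_RIV] += r_frac * dz * (
                    din_in - tracers[I_DIN, 0]
                    + ep[E_NC] * (c_in - tracers[I_POC, 0]
                                  - tracers[I_PHY, 0] - tracers[I_ZOO, 0]))
                ledger[d, L_P_RIV] += r_frac * dz * (
                    dip_in - tracers[I_DIP, 0]
                    + ep[E_PC] * (c_in - tracers[I_POC, 0]
                                  - tracers[I_PHY, 0] - tracers[I_ZOO, 0]))
                ledger[d, L_O2_RIV] += r_frac * dz * (do_riv - tracers[I_DO, 0])
                ledger[d, L_DIC_RIV] -= r_frac * dz * tracers[I_DIC, 0]
                tracers[I_PHY, 0] *= 1.0 - r_frac
                tracers[I_ZOO, 0] *= 1.0 - r_frac
                tracers[I_DIC, 0] *= 1.0 - r_frac
                tracers[I_POC, 0] += r_frac * (c_in - tracers[I_POC, 0])
                tracers[I_DIN, 0] += r_frac * (din_in - tracers[I_DIN, 0])
                tracers[I_DIP, 0] += r_frac * (dip_in - tracers[I_DIP, 0])
                tracers[I_DO, 0] += r_frac * (do_riv - tracers[I_DO, 0])
            # --- archive accumulation
            for i in range(n):
                arch_t[d, i] += temp[i]
                for j in range(N_TRACERS):
                    arch_tr[j, d, i] += tracers[j, i]
        inv = 1.0 / n_sub
        for i in range(n):
            arch_t[d, i] *= inv
            for j in range(N_TRACERS):
                arch_tr[j, d, i] *= inv
        arch_sed[d, 0] = sed[0]
        arch_sed[d, 1] = sed[1]
        arch_sed[d, 2] = sed[2]
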