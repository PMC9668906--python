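# Methods

This note documents the model equations, the choices made where the design
was genuinely open, the synthetic-forcing generator's scope, and the
numerical conventions. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Scope and the 3-D → 1-D reduction

The target system is a deep, warm monomictic lake (never freezing, mixing
top-to-bottom once per winter). The full problem is three-dimensional —
momentum, continuity, horizontal advection — but stratification, winter
overturn and hypolimnetic oxygen are vertical phenomena, so the package
solves a single column and replaces resolved circulation with two
parameterizations:

* **wind-driven diffusivity** K(z) = K_bg + c·u*³·exp(−z/L) / (1 + N²/N₀²)^p,
  with u* the waterside friction velocity from the over-lake wind
  (land wind × 1.2) and N² the local buoyancy frequency;
* **convective adjustment** — statically unstable contiguous layer groups
  are pooled to their volume-weighted means (temperature and all tracers
  together), iterated until the density profile is non-decreasing with
  depth. The algorithm is the stack ("pool adjacent violators") form;
  within the monotone range of the equation of state its fixed point equals
  repeated pairwise mixing, which the tests exploit as a brute-force
  oracle. Near the 3.98 °C density maximum the pooled result is still
  conservative and stable, but the pairwise equivalence is only exercised
  above 5 °C.

Horizontal exchange, seiches, ice and the two-basin structure are out of
scope. Momentum is not solved, so the bottom-friction condition of the 3-D
problem has no analogue here.

## Physics

* **Equation of state:** Kell (1975) rational polynomial, salinity 0,
  valid −0.5..40 °C, ρ(4 °C) = 999.972 kg/m³.
* **Surface heat budget** (positive into the lake): net shortwave
  (albedo 0.07), with fraction β = 0.45 absorbed in the surface layer and
  the remainder attenuated by Beer–Lambert extinction
  k = 0.35 m⁻¹ + 2·10⁻⁴·POC (self-shading); longwave via Brutsaert
  clear-sky emissivity 1.24·(e_a/T_a)^{1/7} with cloud factor
  (1 + 0.22·CC²) against grey-body emission (ε = 0.97); bulk sensible and
  latent fluxes with transfer coefficients 1.3·10⁻³ and a fixed relative
  humidity of 0.75 (the generator does not synthesise humidity; a constant
  mid-latitude value keeps the latent flux responsive to the air–water
  temperature contrast). Shortwave reaching the bed is absorbed in the
  bottom layer so the column heat budget closes.
* **Mixing constants:** c = 3·10⁴ s²/m (K at the surface ≈ 10⁻² m²/s under
  a 6 m/s lake wind), L = 15 m, N₀² = 3·10⁻⁵ s⁻², p = 1.5,
  K_bg = 8·10⁻⁶ m²/s. K_bg represents internal-wave background mixing in a
  large deep basin; it also controls how much the hypolimnion warms during
  stratification and therefore how reliably the following winter's surface
  cooling reaches bottom density. These five constants were calibrated once
  so the default scenario reproduces the qualitative limnology of the study
  system — overturn in most winters (February–March), ≥ 2 °C summer
  stratification for months, hypolimnetic DO minima of a few mg/L — and are
  all exposed in the `physics:` config block.
* **Boundary conditions:** no heat flux through the bottom; river inflow
  and the matching outflow act on the surface layer (the outflowing canals
  of the prototype system are surface withdrawals).

## Ecosystem

State per layer: PHY, ZOO, POC (mgC/m³), DIN (µgN/L), DIP (µgP/L),
DO (mg/L), plus a diagnostic DIC tracer (below). Sediment pools: organic C,
N, P per m².

Process forms (all rates per day, Q10 = 2 temperature scaling around
20 °C):

* growth = µ_max · f_T · I/(K_I + I) · min(f_N, f_P) · PHY with
  Michaelis–Menten f_N, f_P (Liebig minimum — phosphorus is the operative
  limiter under the default N:P loading ratio);
* Ivlev grazing g_max·(1 − e^{−λ(PHY−P₀)})·ZOO with assimilation 0.7; the
  unassimilated fraction egests to POC;
* linear respiration and mortality; zooplankton respiration excretes
  directly to DIN/DIP by default. The alternative "via POC only" closure is
  implemented by routing the respiration rate into mortality (a fixed-
  stoichiometry POC pool cannot absorb N and P without carbon), switchable
  with `excrete_direct: false`;
* first-order POC decomposition, Monod-limited by DO (half-saturation
  0.5 mg/L) so oxygen cannot be driven negative;
* reaeration: piston velocity 1 m/day against Benson–Krause saturation;
  supersaturation is capped at 1.2 × saturation (bubble escape), with the
  vented mass ledgered;
* sediment: single-pool first-order decay (Q10-scaled by bottom
  temperature). Decay proceeds regardless of oxygen (anaerobic pathway);
  the oxygen demand actually drawn from the bottom layer is capped so DO
  stays non-negative and the unmet remainder is ledgered. N is released in
  pool stoichiometry; P release is multiplied by 1 + a·K/(K + DO)
  (a = 3, K = 2 mg/L), the redox legacy-phosphorus term.

Stoichiometry is fixed Redfield (C:N:P = 106:16:1 molar;
O₂:C = 32:12 by mass). Rate defaults (µ_max = 2, grazing 0.3,
decomposition 0.015, sinking 0.3 / 3 m per day for PHY / POC, sediment
decay 1.2·10⁻³) are literature-plausible values calibrated jointly with
the physics constants to give near-zero growing-season surface DIP over a
higher subsurface pool and seasonal bottom-DO drawdown of a few mg/L; the
predecessor models from which the prototype system inherited its parameter
set are not published with it, so these are package choices, every one
exposed in the `ecology:` config block and printable with
`monomict list-params`.

### Carbon closure and the DIC diagnostic

Respiration and photosynthesis exchange carbon with a transported DIC
tracer that has no other dynamics. It exists so that total carbon
(water + sediment + DIC) is exactly conserved and the oxygen budget can be
reconciled against biological carbon turnover; it is excluded from the
positivity guarantee (it may run negative, being a cumulative net-
community-production counter, not a modelled CO₂ pool).

### Positivity

Biochemical tendencies are integrated forward-Euler per physics sub-step
with *capped sinks*: all outgoing fluxes of a pool are jointly rescaled so
the pool cannot be driven below zero within the sub-step, and each flux
keeps its paired destination, so elemental conservation is exact rather
than repaired by clipping.

## Coupled stepping

Operator splitting per sub-step (default dt = 600 s, 144 steps/day —
diffusion is implicit, so dt is limited only by the forcing resolution,
the sinking CFL bound w·dt ≤ Δz and the ecology positivity bound, all
enforced by `stability_check`):

1. surface heat flux and shortwave absorption;
2. implicit vertical diffusion of heat and all tracers (one factorisation,
   shared K);
3. convective adjustment of heat and tracers together;
4. sinking (first-order upwind; bottom export accrues to sediment);
5. biochemical reactions (capped-sink Euler);
6. reaeration, sediment exchange, supersaturation venting;
7. river inflow/outflow on the surface layer.

The archive stores daily means (turnover detection operates on daily
values); `archive_every` subsamples the daily archive and never changes
the dynamics. Every boundary flux (heat, C, N, P, O₂ — air, sediment,
venting, rivers) accumulates in a per-day ledger, and
`SimOutput.budget_residuals()` closes Δstock against the ledger; the test
suite requires < 10⁻⁸ relative on closed columns and observes ~10⁻¹³.

A `suppress_mixing` switch disables convective adjustment and zeroes
wind-driven K below 20 m — the artificial permanently-stratified
counterfactual used to isolate the effect of winter overturn on bottom
oxygen.

## Synthetic forcing

The generator emulates the *statistical structure* of the prototype
forcing, not any particular year:

* daily meteorology = sinusoidal climatology + optional linear trend
  (air temperature, centred on the series midpoint so the configured mean
  is the series mean) + AR(1) anomalies (φ = 0.7) clipped to physical
  domains. Defaults: air temperature 14 ± 11.5 °C (minimum late January),
  wind 3.2 ± 0.7 m/s (winter maximum), cloud 0.65 ± 0.10, precipitation
  totalling 1700 mm/yr with a mean-preserving lognormal AR(1) multiplier;
  shortwave is the clear-sky top-of-atmosphere curve at 35.25° N ×
  transmissivity 0.75 × (1 − 0.65·CC), so cloudy anomalies dim the lake
  consistently;
* `winter_air_offset` (Dec–Mar) and `winter_wind_multiplier` (Nov–Apr) are
  experiment knobs for the driver-sensitivity ensembles;
* nutrient loading: the `biwa-history` preset is piecewise-linear — rise
  from 1955 to a 1975 peak, strict decline 1980→2000, 2010 = 50% of 2000,
  flat outside; TN = 12 × the TP shape. `constant` holds a configured
  level;
* rivers: flow = baseflow + runoff coefficient × catchment area ×
  10-day-smoothed precipitation (default catchment 3.8·10⁹ m², runoff 0.55
  — ≈ 4·10⁹ m³/yr against a 2.8·10¹⁰ m³ column volume, a ~6–7-year
  residence time); river temperature equals same-day air temperature
  floored at 0 °C; 60% of TN/TP enters as DIN/DIP and the residual TP as
  Redfield-stoichiometry POC, with concentrations scaled so each calendar
  year's mass closes on the annual load exactly. TN beyond the POC-bound
  share is treated as retained in the catchment, keeping the delivered
  N:P consistent with the tracer stoichiometry.

What the generator does **not** emulate: humidity and pressure weather,
synoptic storm structure beyond AR(1) persistence, instrument-era
inhomogeneities of real records, spatial forcing gradients, and real
historical sequences. Passing tests therefore demonstrate that the coupled
mechanisms behave correctly under realistic statistical forcing — not that
the package reproduces any specific observed year.

## Analysis conventions

* **Turnover timing** is days past January 1 of the labelled year
  (January 1 = 0); the search window is December 1 of the preceding year
  through April 30, so December detections are negative. The criterion
  must hold for a single daily-archive day (no persistence requirement).
  Gaps ≤ 7 days in monitoring input are linearly interpolated; larger gaps
  are a data error.
* **Curve-shape cross-check:** "turnover-like" requires a trailing-14-day
  bottom-temperature fall ≥ 0.05 °C simultaneous with a bottom-DO rise
  ≥ 0.5 mg/L. The DO jump carries the discrimination: in this column the
  deep water is already near the winter mixed temperature when overturn
  completes, so the temperature drop is small (~0.1–0.3 °C).
* **Predictor aggregation:** cold season = November 1 (Y−1) to
  April 30 (Y). WS uses land-station wind (the 1.2 factor would only
  rescale the predictor and cannot change importance ranks). DD is the
  mean bottom-minus-surface density difference; POC the mean surface
  concentration.
* **Forest importance:** bagged `DecisionTreeRegressor`s
  (max_features = p/3), %IncMSE from out-of-bag permutation against the
  forest-aggregated OOB MSE, node purity as the summed impurity decrease,
  and variance explained as 1 − MSE_OOB/var(y) (out-of-bag, the
  convention chosen since the prototype analysis does not state its fit
  statistic). Failed-turnover years are excluded from the response by
  default; a censored mode (timing = window end, day 120) is available.
* **Regressions:** OLS with t-distribution slope CIs; the period split
  assigns the boundary year to "before". No multiple-testing correction is
  applied (raw R² reporting).

## Numerical conventions and degenerate inputs

Heat content bookkeeping uses a constant ρ₀c_p (1000 kg/m³ ×
4186 J/kg/K), so ledger closure is exact by construction. Ties in the
hypoxia index break to the first occurrence. Zero observation range flags
NRMSE as undefined rather than dividing by zero. Unknown config keys are
rejected. NaN/Inf anywhere in a run aborts with the first offending day
and layer. Re-running a config (hash-identical, same seed) is bit-identical.

## Problem sizes

The default experiments are sized for a desk machine: the emergence run is
6 simulated years at dt = 600 s on 37 layers; the driver ensembles use 20
seeds × 2-year runs per scenario; the forest and regression recovery
experiments use 30-row tables × 300 trees and 100 seeded replicates. All
sizes are parameters.

## Known limitations

* One phytoplankton pool, fixed stoichiometry: no N-fixation,
  denitrification, silica or carbonate chemistry; "bacteria" are implicit.
* The 1-D overturn surrogate cannot represent differential basin mixing or
  horizontal intrusions; bottom temperature changes at turnover are
  correspondingly gentler than observed.
* River inputs enter the surface layer only (no plunging inflows).
* The sediment is a single well-mixed reactive pool with no burial
  horizon; long-term legacy dynamics beyond first-order decay are not
  represented.
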