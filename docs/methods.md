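# Methods

## Discrimination model

The core of the package is the steady-state model of photosynthetic ¹³C
discrimination with explicit mesophyll, photorespiratory and day-respiratory
terms,

Δ = a + (b − a)·ci/ca − (b − a_m)·A/(g_m·ca) − f·Γ*/ca
    − R_d/(A + R_d)·e·(ci − Γ*)/ca,

valid for A + R_d > 0 and Γ* < ci < ca. Assumptions carried throughout:

- the substrate of day respiration is recent assimilate (the e-term uses the
  current ci and Γ*), appropriate in daytime when A ≫ R_d;
- leaf temperature equals chamber air temperature;
- g_m is constant over the season (a user-supplied g_m can replace the
  default; `g_m = inf` disables the mesophyll term, and
  `light_inhibited=True` zeroes R_d inside the model while the night-time
  efflux keeps the full response);
- all fluxes and conductances are per all-sided needle area.

Temperature responses are Arrhenius-type, referenced to 25 °C:
Γ* = 42.75·exp[37830·(T−25)/(298·R·(T+273.15))] µmol mol⁻¹ and
R_d = R_d0·exp[H_α·(T−25)/(298·R·(T+273.15))], R = 8.3145 J mol⁻¹ K⁻¹.
(R_d0, H_α) are fitted to night-time chamber effluxes by nonlinear least
squares (initial values: mean efflux and 5·10⁴ J mol⁻¹). The fit demands at
least five records spanning at least 5 °C — below that span H_α is
practically unidentifiable (a constant-temperature sample is rank
deficient).

### iWUE inversions

The "complex" isotope inversion is **defined** as the exact algebraic
inverse of the model above solved for iWUE = (ca − ci)/1.6:

iWUE = ca/1.6 · [b − Δ − r·e − (b − a_m)·A/(g_m·ca) − f·Γ*/ca + r·e·Γ*/ca]
       / (b − a − r·e),  r = R_d/(A + R_d).

Published renderings of this expression sometimes drop the −r·e term from
the numerator; the composition test (model ∘ inverse = identity to 1e-10
relative on random physical inputs) is the authoritative contract and fixes
every sign. The simple inversion ca·(b′ − Δ)/(1.6·(b′ − a)), b′ = 27 ‰,
is the exact inverse of the two-term model Δ = a + (b′ − a)·ci/ca.
Nonphysical outputs (iWUE < 0 or > ca/1.6) are flagged in the log, never
clipped.

For pool-based inversions, ca and δ¹³C_air are daytime means of the
ambient (pre-closure) environmental series, not the in-chamber drawdown;
A and T_l are daytime means of the QC-passing chamber fluxes.

## Chamber closures

A non-airtight chamber of volume V (1 dm³ default; 2.1 dm³ for free-shape
shoots) is closed for 65 s while sample air is drawn at q (default
1 dm³ min⁻¹ — the draw of a typical isotope analyser; the true value is a
free config parameter) and replaced by ambient leak-in. Each species obeys
dC/dt = (q/V)(C_amb − C) − F·S/n_air with the exponential solution
C(t) = C_eq + (C₀ − C_eq)e^(−kt), k = q/V. The flux per needle area S is
F = n_flow·(C_amb − C_eq)/S with molar sample flow n_flow = q·P/(R·T):
the equilibrium-deficit form is algebraically consistent with the initial
slope on this model class but more robust for 65 s closures.

Numerical choices:

- **k is held fixed at q/V** (known hardware constants). A 65 s closure
  spans under one dilution time constant, so freeing k lets it trade off
  against C_eq and occasionally produces wild fluxes on noisy traces;
  `fit_rate_constant=True` frees it for diagnostics.
- Fit windows: 5–50 s for the 0.5 s isotopologue channels, 5–35 s for the
  5 s bulk CO₂/H₂O channels; at least 6 points required.
- A perfectly flat trace (zero equilibrium deficit) is returned as flux 0
  with a `flat` flag rather than fitted.
- ¹²CO₂/¹³CO₂ ambient mole fractions are split from total CO₂ using
  R_VPDB = 0.0111802; δ¹³C of the assimilation flux is
  (F13/F12/R_VPDB − 1)·1000, defined only for F12 > 0 (night closures get
  NaN).

QC (strict inequalities, matching the screening convention): δ¹³C is
discarded when the CO₂ flux is **below** 0.5 µmol m⁻² s⁻¹; H₂O flux is
discarded when chamber RH **exceeds** 75 %. QC nulls entries, never alters
retained values. Daily summaries are flux-weighted means over the daytime
window [sunrise + 2 h, sunset − 2 h]; sunrise/sunset are inputs, not
computed from solar geometry.

## Carry-over analysis

Leaf pools integrate the daily assimilate signal as
X*_t = Σ_{i=0..n} λ^i X_{t−i} / Σ λ^i, read as geometric decay because λ
is the fraction of the current day's pool retained into the next day; a
`flat=True` switch provides the equal-weight alternative reading for
sensitivity checks. λ = 1 reproduces the unweighted (n+1)-day moving
average and n = 0 the identity. The grid search covers n = 0–12 d and
λ = 0.1–1.0 in steps of 0.1, computes Spearman ρ per cell on a common
date alignment (the overlap at the deepest look-back, so cells are
comparable), and reports the full surface; the argmax is tie-broken toward
smaller n, then larger λ — the most parsimonious memory — because
neighbouring cells are often near-equivalent.

Needle generations are combined only for pools whose 0N−1N offset is
stable: sucrose by plain averaging, WSC after subtracting the configured
0.6 ‰ 0N enrichment (the combined series then represents 1N, the
generation the chambers enclose). Starch, pinitol and TOM are refused
without `force=True`.

In the pipeline, daily driver series (modeled δ¹³C, iWUE_gas) can lose
whole days to QC; interior gaps are time-interpolated before carry-over
integration (logged), while `integrate_carryover` itself stays strict and
drops dates without full look-back coverage.

## Synthetic season generator

The generator emulates a boreal Scots pine campaign (May–mid-October,
sunrise 04:00, sunset 22:00) with known truth at every stage:

- **Environment**: half-sine diurnal PAR scaled by season and a per-day
  cloudiness draw; temperature = seasonal sinusoid + diel cycle + day-level
  Gaussian noise (sd 2.5 °C); RH anti-correlated with the temperature
  anomaly (−1.8 % per °C, day-level noise sd 8 %, clipped to 25–97 %);
  e_s from the Tetens form, VPD = e_s(100 − RH)/100; ca = 405 ppm and
  δ¹³C_air = −8.5 ‰ constant; an optional dry period draws soil moisture
  linearly down to a 0.10 m³ m⁻³ floor. Day-level variability is sized so
  the daily assimilate δ¹³C spreads ~±2 ‰ around −26.5 ‰ and daytime iWUE
  spans ~55–120 ppm, the magnitudes typical of boreal pine seasons.
- **Gas exchange**: net A from a saturating light response (A_max = 8
  µmol m⁻² s⁻¹, all-sided) with a Gaussian temperature modifier; stomata
  follow the optimal-control schedule iWUE = ca·√VPD/(1.6·(g₁ + √VPD)),
  g₁ = 1.6 kPa^0.5 (boreal pine), plus a drought add-on below a soil
  moisture threshold; g_s = A/iWUE, E = g_s·VPD/P, ci = ca − 1.6·iWUE.
  Night records carry −R_d(T). Truth Δ and δ¹³C_A are computed by the same
  discrimination module that analyses them, so forward/backward consistency
  is exact by construction; a schedule pushing ci below Γ* is an error.
- **Closure traces** follow the dilution mass balance exactly; the ¹³CO₂
  trace is constructed so the isotopologue flux ratio encodes the record's
  true δ¹³C_A (night: a fixed respired signature of −26 ‰). One noise sd
  (ppm) drives the CO₂ channels; the ¹³CO₂ channel is scaled by the
  isotopologue abundance and H₂O by 100×.
- **Pools**: sucrose = (n = 4, λ = 0.8) weighting of the daily
  assimilation-weighted δ¹³C_A; pinitol invariant (−31.0 ‰ in 1N, −30.1 ‰
  in 0N); WSC = 40 % pinitol (−31 ‰ end-member for both generations) +
  60 % sugar signal, 0N offset +0.6 ‰; starch invariant; TOM tracks the
  weighted signal during the needle growth window (offset −1.3 ‰ for
  structural fractionation) and freezes at its window mean afterwards,
  invariant −29.6 ‰ in 1N. Noise defaults are the analytical precisions of
  the respective methods: 0.1 ‰ bulk, 0.24 ‰ sucrose, 0.19 ‰ pinitol.

What the generator does **not** emulate: radiative transfer, soil-water
dynamics, phloem export and its isotopic preference, chamber warming,
instrument drift, water-vapor cross-sensitivity, or any particular year's
weather trajectory. The hypothesized two-compartment (cytosol/vacuole)
sucrose pool is not modeled; the single geometric memory is the operative
approximation. Passing tests therefore demonstrate numerical correctness
and statistical recoverability under idealized noise, not field accuracy.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` seeds carried in
the configs; identical config + seed gives bit-identical outputs. The
test suite runs the full chain on short seasons (a rain-free week at
30-min resolution for the zero-noise identity checks, six summer weeks at
hourly resolution for the pipeline contract) and uses 100–200-replicate
Monte Carlos for recovery checks; the carry-over recovery uses the full
season sampled every 4 days (39 dates). The demo season is the full
default season at 10-min environmental resolution with closures every
2 h. The zero-noise end-to-end checks use a rain-free, low-RH week so the
RH > 75 % screen does not alter the record set being compared — with wet
records present the chamber and model series legitimately diverge because
the model loses its transpiration input.

## Known limitations

- The exponential closure fit assumes the dilution model is exact; real
  chambers add wall adsorption and mixing lags that are only screened (RH
  filter), not modeled.
- Affine analyser calibration is available as a hook
  (user-supplied coefficients) and defaults to identity; synthetic data
  needs none.
- The (n, λ) surface is intrinsically flat near its optimum — neighbouring
  memories are near-equivalent weightings — so single-cell argmax reporting
  without the full surface would overstate precision; the full surface is
  always returned.
- iWUE inversions propagate pool δ¹³C noise through a factor ≈ ca/(1.6·Δ
  sensitivity) ≈ 11 ppm per ‰, so per-date isotope-based iWUE carries
  several-ppm uncertainty at analytical precision.
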