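# pinedisc

Leaf-level carbon-isotope analysis for Scots pine (*Pinus sylvestris*)
chamber campaigns: estimate the δ¹³C of new assimilates from shoot-chamber
isotopologue fluxes and from the steady-state photosynthetic discrimination
model, invert δ¹³C of leaf carbon pools (sucrose, pinitol, WSC, starch,
TOM) to intrinsic water-use efficiency (iWUE), and quantify the multi-day
carry-over of the assimilate signal in leaf pools. A synthetic-season
generator with known ground truth makes every stage testable end to end.

The package is aimed at tree ecophysiologists and stable-isotope
researchers who run automated shoot chambers coupled to isotope-capable
gas analysers, or who reconstruct iWUE from compound-specific or bulk
δ¹³C of needles.

## The model

Photosynthetic ¹³C discrimination Δ (‰) is modeled as

```
Δ = a + (b − a)·ci/ca − (b − a_m)·A/(g_m·ca) − f·Γ*/ca
    − R_d/(A + R_d) · e · (ci − Γ*)/ca
```

with stomatal diffusion fractionation a = 4.4 ‰, carboxylation b = 29 ‰,
mesophyll transfer a_m = 1.8 ‰, photorespiration f = 8 ‰ (11 ‰ as a
sensitivity option), day respiration e = −6 ‰, mesophyll conductance
g_m = 0.127 mol m⁻² s⁻¹ per all-sided needle area, and Arrhenius-type
temperature responses for the compensation point Γ* (42.75 µmol mol⁻¹ at
25 °C) and mitochondrial respiration R_d (parameters fitted to night-time
chamber fluxes). δ¹³C of assimilates follows from
δ¹³C_A = 1000·(δ¹³C_air − Δ)/(Δ + 1000).

iWUE = A/g_s (ppm) is obtained three ways: from chamber fluxes
(g_s = E·P/(e_s − e_a)), from pool δ¹³C through the exact algebraic
inverse of the full model solved for (ca − ci)/1.6, and through the simple
two-term inverse ca·(b′ − Δ)/(1.6·(b′ − a)) with b′ = 27 ‰. Carbon pools
integrate the daily assimilate signal with geometric previous-day weights,
X*_t = Σ λ^i X_{t−i} / Σ λ^i (i = 0…n); the (n, λ) memory is recovered by
a Spearman-correlation grid search over n = 0–12 d, λ = 0.1–1.0.

Chamber closures (65 s, non-airtight, sample flow compensated by ambient
leak-in) follow the first-order dilution mass balance
dC/dt = (q/V)(C_amb − C) − F·S/n_air; fluxes come from the fitted
equilibrium deficit of the exponential solution. δ¹³C entries are
discarded when the CO₂ flux is below 0.5 µmol m⁻² s⁻¹ and H₂O fluxes when
chamber RH exceeds 75 %.

## Worked example

Run the full synthetic season (environment → gas exchange → chamber
closures → fluxes → δ¹³C series → iWUE → carry-over):

```
pine-disc demo --seed 7 --out demo_out
```

which prints (about nine seconds on one core):

```
n_closures: 2004
n_qc_co2_fail: 668
n_qc_h2o_fail: 908
fitted_r_d0: 0.8
fitted_h_alpha: 40000.0
delta13c_a_picarro_mean: -26.7
delta13c_a_model_mean: -25.7
carryover_best_n: 4
carryover_best_lambda: 0.9
carryover_best_rho: 0.86
iwue_sucrose_vs_gas_pearson_r: 0.9
iwue_sucrose_vs_gas_mean_offset_ppm: -10
iwue_gas_mean_ppm: 83
iwue_iso_complex_mean_ppm: 74
```

Reading this: 2004 chamber closures were fitted; the 668 closures failing
the CO₂-flux screen are night and low-light records. The respiration fit
recovers the generating temperature response (R_d0 = 0.8 µmol m⁻² s⁻¹,
H_α = 40 kJ mol⁻¹) from the night fluxes. The chamber-derived and modeled
seasonal mean assimilate δ¹³C agree to within 1 ‰ (the gap reflects the
RH > 75 % screen removing humid records from the model's transpiration
input). The sucrose carry-over grid search finds (n = 4 d, λ = 0.9), one
grid cell from the generating memory (4 d, 0.8), and sucrose-derived iWUE
tracks gas-exchange iWUE (r = 0.9) with a −10 ppm mean offset driven by
the carry-over smoothing of the gas-exchange series.

Stages can also be run individually (`pine-disc simulate | fluxes | model
| iwue | carryover`, see `--help`), all governed by one YAML config.

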