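# flightpower

How efficiently does a flying animal turn metabolic energy into aerodynamic
work? `flightpower` is a Python library for estimating the **conversion
efficiency of animal flight**, η = P_mech / P_met, from wind-tunnel
experiments on small bats and birds. It implements the complete analysis
chain used for a ~9 g insectivorous bat flown at 3–9 m/s:

- **Mechanical power output** from transverse wake velocity planes
  (tomographic PIV style): background homogenization, vorticity-magnitude
  masking, streamfunction (Helmholtz) reconstruction of the in-plane flow,
  kinetic-energy flux P = ρ⟨∬ ½|u′|²(U∞+u) dA⟩, net-drag correction
  D_net = ρ∬u(U∞+u) dA, and weight support from the first vorticity moment
  F_v = ρ⟨∬U∞(y−y₀)ω_x dA⟩, with half-wake mirroring and sequence
  selection (>1 wingbeat, F_v within ±20% of body weight).
- **Metabolic power input** from ¹³C-labelled sodium-bicarbonate washout:
  single-pool isotope dilution with exponential resting decay, a flight
  window that steepens the washout, fuel conversion factors (21.1 J/ml CO₂
  for glycogen, 23.7 for a mixed RQ 0.88 diet) and the study's selection
  filters (flight fraction ≥ 60%, |Z| ≤ 2 within 1 m/s speed bins, ≥ 4
  flights per individual).
- **Power curves** P = k₁U³ + k₂/U + k₃ fitted as linear mixed models with
  individual random intercepts, with the profile term k₃ pinned to half the
  power at minimum power speed, weight-normalized speeds
  U* = U(W_ref/W)^(1/6), and characteristic speeds
  U_mp = (k₂/3k₁)^(1/4) and U_mr (tangent from the origin).
- **Two aerodynamic models** for comparison: the classic fixed-wing
  decomposition (induced ∝ 1/U, parasite ∝ U³, constant profile power) and
  a quasi-steady flapping model with a Strouhal-dependent induced-power
  factor and red-flag validity indicators.
- **Four efficiency estimators** (binned means, median variant, fitted-model
  ratio, within-individual ±0.5 m/s pairing), muscle efficiency
  η_fm = 1.1·P_mech/(P_met − BMR), and the underestimation analysis against
  the fixed-23% prediction P_met = 1.1(P_mech/η + BMR).
- **A cross-species meta-analysis**: efficiency for 16 bird + 8 bat species
  from literature metabolic series and modeled mechanical power, and the
  allometric scaling fit log₁₀η(%) = 0.24·log₁₀M(g) + 0.49 as a mixed model
  with species random intercepts and speed slopes.
- **Synthetic-data generators** with exact ground truth for every stage
  (Lamb–Oseen vortex-pair wakes, isotope washout traces, power records,
  species tables), so the whole pipeline is testable without any downloads.

## Worked example

`examples/` holds one short script per capability. For instance
`python examples/aerodynamic_power_models.py` prints:

```
fixed-wing: U_mp = 4.3 m/s, U_mr = 7.0 m/s
flapping  : U_mp = 4.6 m/s, U_mr = 6.0 m/s
```

— the two models' minimum-power and maximum-range speeds for the study
morphology (8.9 g, 0.23 m span). `python examples/washout_metabolic_power.py`
simulates a washout trace and recovers the flight cost:

```
flight VCO2        : 2.87 ml/min (truth 2.84)
metabolic power    : 1.010 W
```

and `python examples/power_curves_and_efficiency.py` fits both power curves
to synthetic study-scale records and prints per-bin efficiencies rising
from ~7% at 5 m/s to ~12% at 9 m/s, with a fitted-model-ratio average of
~9% — a third to a half of the 23% conventionally assumed, which is why
fixed-efficiency models underestimate this bat's flight costs by nearly
half. `examples/wake_power_from_piv.py` and
`examples/efficiency_mass_scaling.py` cover the wake operators and the
cross-species scaling law.

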