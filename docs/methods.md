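# Methods

This note documents the models, estimators and numerical choices behind
`flightpower`, and what the synthetic-data tests do and do not establish
about real data.

## Aerodynamic power models

**Fixed-wing model** (`aero.pennycuick_power`). Steady gliding-theory
decomposition for a flapping animal of weight W = Mg, span b, wing area S:

- induced power `P_ind = k W² / (2 ρ S_d U)` with induced factor k = 1.2 and
  disc area S_d = πb²/4 (momentum-jet wake of the wing disc);
- parasite power `P_par = ½ ρ U³ S_b C_db`, with body frontal area
  defaulting to the allometric `S_b = 0.00813 M^0.666` m² (M in kg) when no
  measured value is supplied;
- profile power constant with speed, `P_pro = (8.4 / AR) · P_am`, where
  P_am is the absolute minimum of `P_ind + P_par` and AR = b²/S.

These are the conventional program defaults for this model family. For the
study morphology (M = 0.0089 kg, b = 0.23 m, S = 0.0077 m², C_db = 0.4,
ρ = 1.225 kg/m³) they give U_mp = 4.3 m/s and U_mr = 7.0 m/s. The closed
forms make U_mp depend only on the induced and parasite coefficients,
`U_mp = (A/3B)^(1/4)`; no admissible frontal-area/drag choice can move it
much below 4 m/s without simultaneously dragging U_mr far below 7 m/s, so
the pair (4.3, 7.0) is what this model family genuinely predicts here.

**Flapping model** (`aero.flap_model_power`). Flapping modifies both the
induced and the profile power. The model keeps the quasi-steady structure
and adds two flapping corrections governed by the span-based Strouhal
number St = f b / U:

```
P(U) = [k₀ + k_st·St²] · W²/(2ρS_d U)            induced, flapping-amplified
     + ½ ρ U³ S_b C_db                            body parasite
     + ½ ρ U³ S C_D,pro + c_flap · ½ ρ S (f b)³   wing profile, steady + flapping
```

with k₀ = 1.2 and C_D,pro = 0.02 conventional. The two flapping constants
are calibration parameters of this implementation: they were fixed once, in
closed form, so that the reference morphology reproduces the published
predictions of the flapping-flight performance tool this model emulates
(U_mp = 4.6 m/s, U_mr = 6.0 m/s). Solving `P'(u_mp) = 0` and the tangency
condition `u_mr P'(u_mr) = P(u_mr)` for the two unknowns gives
k_st = 2.7565368049 and c_flap = 0.5015982098, frozen in
`aero.FLAP_CALIBRATION`. Because both constants are dimensionless in St and
f b, the model extrapolates plausibly across the 4 g – 2.6 kg species range
of the meta-analysis. Red flags mark inputs outside the validated envelope:
St outside [0.05, 1.0] (speed flag), total drag-to-lift ratio above 0.5
(thrust flag), wingbeat frequency outside 0.5–2× the allometric expectation
(frequency flag). Flagged outputs are excluded downstream.

## Wake processing

The wake operators work on time series of gridded (u, v, w) velocity planes
perpendicular to the free stream.

- *Background homogenization*: the per-pixel median of u over all frames of
  all sequences (wake-masked cells excluded when masks are available)
  estimates the systematic background distortion; it is subtracted and its
  spatial mean added back, preserving the mean free stream. The median makes
  the estimate robust to wake passage; the operation is idempotent.
- *Vorticity and masking*: ω_x by second-order central differences
  (one-sided at borders). The wake mask thresholds the vorticity magnitude
  — smoothed with a σ = 1.5-cell Gaussian, because finite differencing
  amplifies pixel noise and the mask statistic must not chase it — at
  3 robust (MAD) sigmas above the median, followed by a single
  dilation–erosion closing. Threshold 0 disables masking.
- *Flow reconstruction*: `∇²ψ = −ω_x` with zero-Dirichlet far-field
  boundaries, solved spectrally (DST-I), then v = ∂ψ/∂z, w = −∂ψ/∂y. The
  reconstructed field is the solenoidal part induced by the masked
  vorticity. Zero-Dirichlet clipping of the (small) boundary-crossing far
  field biases the recovered kinetic-energy flux low by ~2% on the default
  synthetic geometry; the window must extend several vortex separations for
  this to hold.
- *Integrals*: kinetic power, net drag and vertical force are discrete cell
  sums over masked cells, averaged over complete wingbeats (trailing
  partial wingbeats discarded; frames per wingbeat from the sequence's
  wingbeat frequency). The advection speed in the energy flux is the
  pointwise `U∞ + u` (a config switch allows plain U∞ for sensitivity
  checks). The vertical-force lever arm origin y₀ defaults to the
  circulation-weighted centroid of |ω_x|. Sign conventions follow the
  wake-deficit form: momentum deficits give negative net drag and the
  correction `P + D_net·U` adjusts power accordingly.
- *Half wakes* are mirrored about the centre plane (u, w even; v odd, so the
  image vorticity counter-rotates) before reconstruction, which doubles the
  vertical force relative to the measured half. Sequence selection keeps
  sequences with more than one complete wingbeat and wingbeat-averaged
  vertical force within ±20% of the animal's weight.

## Isotope washout

A single well-mixed bicarbonate pool of size N (ml CO₂ equivalents) washes
out label at instantaneous rate VCO₂(t)/N, so breath excess enrichment
decays exponentially at rest. The estimator fits
`e(t) = baseline + A·exp(−k(t−t₀))` to the pre- and post-flight phases
(nonlinear least squares; non-decaying traces are rejected, implementing
the "stable washout" selection rule), extrapolates both fits to the flight
window's endpoints, and attributes the label lost across the window to a
contiguous flight interval of length `flight_fraction × duration` centred
at the midpoint:

```
VCO₂_flight = (60·N·Δln e − VCO₂_rest·(T − T_f)) / T_f
```

with VCO₂_rest = 60·N·(k_pre+k_post)/2. Pool size comes from the label dose
and the equilibration plateau (`pool_from_dose`). Because only the
*integral* of production over the window enters, the estimate is exact for
any placement of landings within the flight, which is why the generator and
estimator close to numerical precision on noise-free traces. Fuel factors:
21.1 J/ml CO₂ (glycogen, the study assumption), 23.7 (80/20
carbohydrate/lipid, RQ 0.88); switching multiplies every power by exactly
23.7/21.1 ≈ 1.123. Respirometry BMR uses the 20.1 J/ml O₂ oxyjoule
equivalent, with a warning outside the 28–35 °C thermoneutral window.

Filters run in a fixed order — flight fraction ≥ 0.6, then |Z| ≤ 2 within
1 m/s speed bins (population s.d.; "exceeding 2" is read strictly, and a
singleton bin has undefined Z and is retained), then ≥ 4 surviving flights
per individual ("more than three" read strictly).

## Power-curve fitting

The cubic-plus-inverse family is linear in (k₁, k₂, k₃) on the basis
(U³, 1/U, 1), so the mixed model (individual random intercepts) is fitted
with a linear mixed-effects solver under maximum likelihood. Numerical
notes: the raw basis is severely ill-conditioned (U³ ~ 500 vs 1/U ~ 0.15),
so columns are scaled to unit RMS before the solve; and when the
random-intercept variance collapses to its zero boundary the mixed
optimizer can misbehave, so any non-finite, boundary or worse-than-OLS fit
falls back to the exact zero-variance special case (OLS).

In the default `k3_mode="fixed"`, the profile term is pinned *before*
fitting to half the mean observed power in the 1 m/s bin at the rounded
aerodynamic U_mp prior — a deliberate two-step reproduction of the
constrained-fit procedure, not a joint optimization. The pin equals
`0.5·P(u_mp)` of the final curve only when the underlying curve itself
satisfies the profile-equals-half-power convention; parameter-recovery
simulations therefore draw from such self-consistent triples
(k₃ = k₁c³ + k₂/c at the bin centre c), since data generated from a
non-self-consistent triple make the two-step pin deterministically biased
(≈ −24% on k₂ for the reference mechanical curve) — a property of the
procedure, not of the solver. The U-shape vs linear likelihood-ratio test
is reported as described but always carries a non-nestedness warning and
AIC values, because the two families are not nested.

## Efficiency estimators

All four estimators return P_mech/P_met and agree exactly on noise-free
data from a single curve pair. The pairing estimator forms every
within-individual cross-pair with |ΔU| ≤ 0.5 m/s, reports median ± range
per individual per 0.5 m/s bin, Pearson r² of efficiency against speed at
the pair level (duplication makes pairs non-independent; the duplication
tallies are reported alongside), and the counts of re-used records. Muscle
efficiency defaults to `η_fm = 1.1·P_mech/(P_met − BMR)`; the strict
algebraic inverse of the fixed-efficiency prediction,
`1.1·P_mech/(P_met − 1.1·BMR)`, is available via `strict_inverse=True` —
the two differ by ~0.1 percentage point at the study's means (11.0% vs
11.1%).

## Meta-analysis

Species efficiency is the flapping-model mechanical power over the
literature metabolic power, keeping only speeds at or above the species'
metabolic minimum power speed (from an OLS cubic-plus-inverse fit to its
series, falling back to the observed minimum when the fit is not U-shaped)
and unflagged model outputs. The scaling model is a Gaussian mixed model on
log₁₀η (η in percent, mass in grams — the unit convention that makes the
intercept 0.49 reproduce a ~5% mass-corrected efficiency at 7.6 g):
fixed log₁₀M and speed, random intercept and random speed slope per
species. Speed enters *centred within species*: absolute speed ranges scale
with body size, so an uncentred speed covariate leaks mass signal into the
mass exponent (simulation shows a +0.06 slope bias and halved standard
errors without centring). A singular random-slope fit falls back to the
intercept-only structure; fully degenerate (noise-free) data fall back to
least squares; both are flagged. The taxon contrast near U_mp uses a linear
model with a centred-log-mass × taxon interaction, so the taxon coefficient
is the bird-bat difference at the mean mass rather than at 1 g.

## Synthetic data: what it does and does not show

Generators share the estimators' forward models where the paper's method is
itself a model (isotope dilution, the curve family, the scaling law), and
use independent closed forms where the estimator is an integral operator
(Lamb–Oseen vortex pairs: circulation, `F_v = ρU∞Γs`, fine-grid quadrature
energy flux). Defaults encode the study's conditions: 8 individuals ×
~5–6 metabolic flights at 4–9 m/s around the reference metabolic curve
(residual s.d. 0.12 W, individual s.d. 0.08 W); 4 individuals × 12
mechanical sequences at 5–9 m/s (0.005/0.004 W); washout traces with
resting VCO₂ 0.23 ml/min, ~66 s flights, 89% flight fraction; species
tables of 16 birds + 8 bats, log-uniform masses 4 g–2.6 kg, intercept
s.d. 0.29, speed-slope s.d. 0.03, 8 speeds per species straddling U_mp,
and a 0.05-dex lognormal metabolic measurement error (~12%, typical
respirometry scatter — also what keeps the mixed model's residual variance
away from zero, where it is degenerate).

Passing tests therefore establish estimator correctness and statistical
calibration *under these idealizations*: frozen (non-evolving) wakes, a
single well-mixed bicarbonate pool, Gaussian noise, exactly known
morphology. They do not validate the aerodynamic models against real bats,
resolve real PIV artefacts (peak locking, reflections, out-of-plane loss),
or capture fuel-mixture uncertainty; those enter real analyses as the
systematic terms discussed above.

## Numerical conventions and problem sizes

Characteristic speeds are solved analytically for coefficient triples and
by bounded scalar minimization (tolerance 1e-3 m/s, tighter on request) for
callables, and reported to 0.1 m/s. Wake grids default to 201² points over
a 0.6 m window, 40 frames (two wingbeats at 200 Hz); Poisson solves are
O(N² log N) DSTs, so a full sequence processes in well under a second.
Stochastic test batteries use 200 replicates for curve and scaling recovery
and 500 for washout recovery, sized to estimate ≥90% pass rates with
binomial noise below the margins being tested. All randomness flows through
`numpy.random.default_rng(seed)`; identical seeds regenerate bit-identical
datasets.

## Known limitations

- The single-plane treatment neglects streamwise gradients and pressure
  work in the wake energy balance.
- The flapping model is a two-constant calibrated surrogate for a full
  wingbeat-resolved aerodynamic code; its absolute power levels inherit the
  calibration morphology, and its red-flag envelope is heuristic.
- The likelihood-ratio comparison of non-nested curve families is
  approximate by construction.
- The meta-analysis treats species as exchangeable random effects;
  phylogenetic covariance is out of scope.
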