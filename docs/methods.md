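# Methods

This note documents the models implemented in `snowflux`, the assumptions
behind them, the synthetic study generator that exercises them, and the
numerical and design choices that were genuinely open.

## Snowpack diffusion-gradient flux

The gradient method treats the snowpack as a homogeneous porous medium in
diffusive steady state. Efflux is

    J_c = theta * tau * D * (P0/(R*T0)) * (T/T0)^0.81 * dC / z

- `theta = 1 - rho/973` — porosity from mean snow density `rho` (g/L,
  numerically identical to kg/m³) relative to pure ice (973 g/L). Pure ice
  has zero pore space; zero density gives porosity 1.
- `tau = theta^(1/3)` — tortuosity, the path-length correction for diffusion
  through the pore network.
- `D = 0.1381e-4 m²/s` — diffusivity of CO₂ in air; `P0/(R*T0) =
  44.613 mol/m³` — molar density of an ideal gas at STP; the
  `(T/T0)^0.81` factor corrects diffusivity to the snowpack temperature.
  `T0 = 273.15 K` (standard temperature; the reference is configurable).
- `dC` in µmol/mol and `z` in m give `J_c` in µmol·m⁻²·s⁻¹; the kernel is
  linear in `dC`, `D`, `theta*tau` and `1/z`, which the unit audit in the
  test suite asserts by scaling.

Aggregation rules (open in principle, fixed here): pit layers are averaged
unweighted (a depth-weighted option exists for profiles with a short bottom
layer); each gradient measurement uses the mean summary of all pits at its
site and date; replicate probe insertions per unit are averaged before the
kernel; the snowpack temperature entering the formula is the pit mean.
Negative gradients (subnivean below surface [CO₂]) produce negative fluxes
that are flagged, never truncated — downstream stages decide how to treat
them (the Q₁₀ fitter excludes non-positive fluxes with a logged count).

The profile linearity QC (`barrier_check`) fits within-snowpack [CO₂] on
depth by OLS: an ice lens or wind crust shows up as nonlinearity. The pass
threshold (R² ≥ 0.90) is a configurable convention; the flag is advisory and
never drops data silently. Fewer than three profile points yields
"insufficient data" rather than an error.

## Q₁₀ temperature response

`flux = A * B^((T+5)/10)`: `A` is the flux at the −5 °C anchor and `B` the
Q₁₀ factor. Fitting is nonlinear least squares on the raw flux scale
(`scipy.optimize.least_squares`), parameterized internally as
`(log A, log B)` so positivity holds by construction; starting values are
`A0 = median flux`, `B0 = 2`.

The parameter covariance is computed from the Jacobian at the optimum. The
default is an HC3 leverage-corrected sandwich estimator rather than the
classical `sigma² (J'J)^-1`: field flux errors are multiplicative (the
scatter grows with the mean), and under that error structure the classical
covariance undercovers (≈89% where 95% is nominal in our simulations) while
the sandwich restores ≈94–95% and remains consistent under homoscedastic
errors. `cov_type="iid"` recovers the classical estimator.

Monte Carlo prediction intervals draw `(A, B)` from the bivariate normal at
the optimum, evaluate the prediction per draw, and take central percentiles
(default 10,000 draws; an explicit seed is required — intervals are
deterministic given one). Draws with `B ≤ 0` (possible at very small n) are
discarded with a warning; a non-PSD covariance falls back to its diagonal.
Year-to-year contrasts at a common temperature are screened conservatively
by interval non-overlap.

## Glucose-addition ANCOVA

`ln(flux_post) = α + β₁ ln(flux_pre) + β₂ Site_mesic + β₃ Site_xeric +
β₄ Treatment + ε`, reference levels site = hydric and treatment = control
(0/1 dummies), so `exp(β₄)` is the multiplicative glucose effect. The
site×treatment interaction is screened first, then pre×treatment, each by a
nested-model F test at α = 0.05; non-significant interactions are removed
and every screening test is logged. The treatment F is the nested-model
comparison in the final model. If an interaction is retained, the treatment
main effect is tested at the covariate mean / averaged over sites
(sum-to-zero contrasts in the interaction columns): with reference-cell
coding that test would be an extrapolated contrast whose conditional
distribution under screening is distorted — orthogonal coding keeps the
type-I error of the full screening-then-test procedure at ≈5–6% (≤7%
asserted over null simulations). Group means are unadjusted arithmetic
means on the original scale. Non-positive fluxes are rejected with an
explicit error (no offset transform). `glucose_c_load` converts an
amendment mass to carbon per area from atomic masses (C 12.011, H 1.008,
O 15.999): 250 g/m² glucose ≈ 100 g C/m².

Degrees of freedom are always `df2 = n − p` for the final model (p = 5 with
both interactions screened out); the 3 sites × 5 pairs design gives (1, 25)
with all 30 plots usable and (1, 24) when one plot is unusable (e.g. a
failed pre-treatment measurement), the structure used in the validation
studies.

## Incubation analyses

**Detection limits.** Below-detection respiration observations are set to
0.01 µg C/g dry soil/day and below-detection NH₄⁺-N to 0.5 µg N/g dry soil
— the lowest reliably detectable values of the respective assays. The
substitution is flag-driven, idempotent, never decreases a value, and the
count is logged.

**Respiration mixed model.** `ln R ~ temperature * C + temperature * date`
with a per-jar random intercept (repeated measures), REML estimation via
`statsmodels.MixedLM`. Julian date is centered at the subset mean to
decondition the temperature×date interaction; coefficients are reported on
the centered scale with the centering constant recorded. The subset is
either all design temperatures {−10, −6, −2, 2, 6} °C or the sub-zero
subset {−10, −6, −2} matching winter field conditions. The three-way
temperature×C×date interaction is fitted by ML, its Wald test logged, and
excluded from the reported model. Denominator df follow a containment rule:
terms constant within jars (temperature, C, temperature×C) are tested
against between-jar df (`n_jars − 4`), terms varying within jars (date,
temperature×date) against within-jar df (`N − n_jars − 2`); this is a
documented approximation of the nested-levels convention used by classical
mixed-model software. Fit quality is summarized by predicted-vs-observed r²
and the observed-on-predicted regression, both computed after
back-transforming to the raw respiration scale (predictions include the
estimated random intercepts). A singular random-effects structure falls
back to a clearly flagged fixed-effects-only fit.

**Nutrient regressions.** Per analyte:
`concentration ~ temperature * C addition` by OLS with temperature and C as
continuous covariates; NH₄⁺-N is fitted on the natural-log scale after
substitution, NO₃⁻-N and TFPA on the raw scale, PO₄-P raw (near its assay
floor). On the 48-jar sub-zero design (3 temperatures × 4 C levels × 4
jars) the model F has df (3, 44). `interaction_effect_table` evaluates the
fitted surface on the design grid with standard errors; log-scale fits are
back-transformed by exponentiating the point and point ± 1 SE. For the
mixed model the grid SE uses the coefficient standard errors without
off-diagonal covariance — a conservative population-level approximation.

## Synthetic study generator

The generator produces every input table with known truth, embodying the
mechanism under study: **labile-carbon depletion**. Respiration is a
first-order decaying labile pool plus a constant recalcitrant baseline,
both scaled by

    g(T) = q^(T/10)            T >= 0
    g(T) = q^(T/10) e^(λT)     T < 0      (continuous at 0)

    R(t) = 1000 k_l g(T) (C_l0 + a) exp(-k_l g(T) t) + b g(T)

with `C_l0` the initial labile pool (mg C/g dry soil), `a` the C addition,
`k_l` the rate constant at 0 °C (1/day), `b` the baseline (µg C/g/day) and
`λ` an extra sub-zero attenuation representing the rapid loss of liquid
water in frozen soil. The closed form makes mass balance exactly testable
(cumulative labile respiration → `C_l0 + a`), and the mechanism produces
the qualitative patterns of interest: respiration rises with temperature,
responds more strongly to C addition when warm, and declines over the
incubation fastest in warm jars (negative date×temperature on the log
scale). First-order kinetics were chosen over Michaelis–Menten for this
closed-form testability. Observed respiration is
`exp(ln R + jar intercept + residual)` with σ_jar = 0.2 and σ_res = 0.3 on
the log scale; observations under 0.01 µg C/g/day are flagged
below-detection.

Defaults (versioned in `snowflux/data/default_truth.yaml`, not in code):
`C_l0 = 0.8 mg C/g`, `k_l = 0.03/day`, `b = 2 µg C/g/day`, `q = 2.5`,
`λ = 0.12/°C` — chosen so 90-day depletion is strong at −2 °C and mild at
−10 °C, with respiration magnitudes (≈0.2–60 µg C/g/day across the design)
typical of organic tundra soils.

Field fluxes follow per-winter Q₁₀ truths (cold winter A = 0.8; warm
winters A = 0.3/0.35; B = 2.5) with *mean-one* lognormal noise
(`exp(σZ − σ²/2)`, σ = 0.2), so the raw-scale least-squares estimand equals
the generator truth and interval coverage has an unambiguous target. Cold
winter soils span −12…−3 °C, warm winters −6…−1 °C. Subnivean [CO₂] is
obtained by inverting the diffusion law through the site-mean pit summary —
making the analysis round trip exact at zero noise — then Gaussian ppm
noise (σ = 10) is added to both readings. Pit densities are site-specific
(260–300 ± 25 g/L), depths ≈ 0.6 ± 0.1 m. The glucose experiment draws
lognormal pre-fluxes per site and multiplies glucose-plot post-fluxes by
the true effect 2.225 with σ = 0.25 log-noise. Nutrient truths encode the
interaction signs of interest (NO₃⁻ and NH₄⁺ decline with C fastest when
warm: β₃ < 0, with the C effect vanishing at −10 °C; TFPA increases with C
when warm: β₃ > 0; PO₄-P sits at a floor with pure noise), with effect
sizes detectable at n = 48.

Because the mechanism is nonlinear in (T, C, t), the estimand of the linear
mixed model on mechanistic data is the least-squares projection of the
noise-free log expected respiration onto the fitted design
(`linearized_lmm_truth`; on the balanced design the GLS and OLS projections
coincide). That projection places the temperature×C coefficient near zero,
so *coefficient recovery* is measured instead on a known-coefficient linear
scenario (`simulate_lmm_scenario`, `lmm_scenario` block of the truth file:
+temperature, +C addition, +temperature×C, −date, −temperature×date), while
the mechanistic generator is exercised end to end through the sign-pattern
checks. What passing tests show — and do not show: the generator emulates
design balance, multiplicative noise and repeated-measures correlation, but
not soil heterogeneity between jars beyond a random intercept, analyzer
drift, snowpack layering/advection (ventilation by wind pumping), or
model-form misfit beyond the depletion mechanism; recovery on synthetic
data demonstrates estimator correctness, not field accuracy.

## Validation studies and problem sizes

The built-in studies (`snowflux.studies`, driven by the test suite and
`scripts/acceptance.py`) use: 1000 random draws for the flux-kernel oracle
comparison (agreement to 1e-12 relative); a 48-observation balanced
temperature grid {−8, −6, −4, −2} °C × 12 with truth (A = 0.5, B = 3) and
σ_ln = 0.2 for Q₁₀ recovery; 500 replicate datasets × 2000 Monte Carlo
draws for interval coverage; 200 replicate 864-observation mixed-model fits
for coefficient recovery; and single 29-plot / 48-jar datasets for the df
structure checks. These sizes give Monte Carlo error comfortably below the
tolerances they are checked against while keeping a full run under a
minute.

## Known limitations

- The flux kernel is a two-point, single-layer steady-state model: no
  layer-resolved diffusion, no advection, no storage term.
- Q₁₀ fits pool sites and treatments within year; no mixed-effects Q₁₀.
- The ANCOVA has no plot-pair random effect (pairs enter only through the
  pre-treatment covariate).
- Mixed-model denominator df are containment approximations, not
  Satterthwaite/Kenward-Roger.
- The incubation analysis treats temperature as continuous; cell-means
  ANOVA is out of scope, as are enzyme-activity and microbial-biomass
  analyses.
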