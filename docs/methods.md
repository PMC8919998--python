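# Methods

## Model

The package predicts steady-state metabolic rate during standing and
walking with backpack loads as

```
Ṁ [W·kg⁻¹] = (Ṁ_rest + a + η(b·S^p + d·S⁴) + Ṁ_grade) · (1 + x·L^y)
```

with all rates expressed per kilogram of body mass (the carried load is
excluded from the denominator, so the same person carrying more mass has a
higher mass-specific rate). The structure separates four ingredients:

- **Resting rate** `Ṁ_rest`: the non-exercise component, estimated from
  lean body mass as `(500 + 22·LBM) kcal·day⁻¹`, converted with
  1 kcal = 4184 J over 86 400 s and divided by body mass. The formula is a
  transcription of the classic lean-body-mass RMR estimate.
- **Speed terms** `a + b·S^p + d·S⁴`: a constant covering standing, a
  fractional power (`p ∈ (0, 1]`) capturing the concave rise at slow to
  moderate speeds, and a quartic term dominating near the walk–run
  transition. Some write-ups express the exponent as `1/c`; the package
  stores `p` directly (and exposes `c = 1/p` for display) to avoid fitting
  a redundant reciprocal.
- **Load multiplier** `1 + x·L^y` with `L` the backpack-to-body-mass
  ratio: equal to 1 unloaded, rising nonlinearly (`y > 1` in the published
  set) so heavy loads cost disproportionately more. By the equation's
  parenthesization the multiplier scales the *entire* bracket including
  the resting rate; a net-of-resting variant exists behind an explicit
  flag for research use only.
- **Extensions**: a terrain coefficient `η` scaling the speed-dependent
  cost (1.0 for treadmill/pavement; a small transcribed table of published
  factors ships with the package) and a graded-walking term
  `Ṁ_grade = 34·S·G·(1 − 1.05^(1 − 1.1^(100G+32)))` for decimal grades.
  The grouping of that expression is the one consistent with a zero cost
  at `G = 0`, a positive cost uphill, and a damped negative cost on
  moderate downhills; grades beyond `|G| = 0.4` trigger an extrapolation
  warning because the source term was not developed for steeper slopes.
  With `η = 1` and `G = 0` the composed equation reduces *bit-identically*
  to the level-walking form — the implementation shares the summation
  order between the two paths so the reduction is exact, not approximate.

The published coefficient set `lcda_backpacking_2022`
(`a=0.19, b=1.78, p=0.58, d=0.27, x=1.96, y=1.36`) is the default
everywhere. Warnings (never errors) are raised for speeds above 2 m·s⁻¹
and loads above 100% body mass, outside the fitted domain.

## Indirect calorimetry

Metabolic rate is computed from steady-state gas exchange as
`Ė [W] = 16.58·V̇O₂ + 4.51·V̇CO₂` with flows in mL·s⁻¹ STPD — a linear
energy-equivalent form derived from the updated nonprotein respiratory
quotient table, kept in a single provenance-tagged constant block. The
assumed-RER path (`V̇CO₂ = 0.85·V̇O₂` by default) serves datasets that
reported only V̇O₂. Steady-state quality control mirrors laboratory
practice: the coefficient of variation between the two 30-s halves of the
final minute must be below 10% for each gas (two-point sample SD, i.e.
`|x₁−x₂|/√2`, over the mean), and the pooled RER must lie in the
respiratory-quotient range `[0.7, 1.0]`, both bounds inclusive. Readers
never guess units: gas columns are tagged mL·s⁻¹ in the schema and an
L·min⁻¹ converter is provided.

## Fitting

Trial data are clustered (each participant contributes ~20 trials), so the
model is fit with an additive participant random intercept:

```
Ṁᵢⱼ = f(condᵢⱼ; θ) + uᵢ + εᵢⱼ,   uᵢ ~ N(0, τ²),  εᵢⱼ ~ N(0, σ²)
```

Rather than depending on a specific nonlinear mixed-effects engine, the
package uses a profiled penalized least-squares scheme. For a fixed
variance ratio `λ = σ²/τ²` the intercepts have the closed-form ridge/BLUP
solution `uᵢ = Σⱼ rᵢⱼ/(nᵢ + λ)`, so they are profiled out inside a single
bounded trust-region nonlinear least-squares solve over θ
(`scipy.optimize.least_squares`, bounds `p ∈ [0.1, 1]`, `y ∈ [0.5, 3]`,
`b, d, x ≥ 0`, `a ∈ [−10, 10]`). Between rounds, σ² and τ² are
re-estimated from the marginal residuals by the one-way ANOVA method of
moments (with a degrees-of-freedom correction charging the six fixed
parameters to the within-cluster estimator), and the solve repeats until
the objective is stable to a relative 1e-8 and λ stops moving. For this
balanced, intercept-only structure the scheme tracks a REML fit closely.
Numerical properties worth knowing:

- the trust-region solve is monotone within each round (recorded in the
  fit trace and asserted in tests);
- noise-free data drive `τ̂², σ̂² → 0`, the ratio is set to `λ = ∞`
  (plain least squares, `u ≡ 0`), and the generating coefficients are
  recovered to machine-level accuracy;
- designs that cannot identify all six parameters (fewer than two loads,
  three speeds, or two participants) are rejected with an explicit error;
  non-convergence is flagged on the result, never silent.

One estimator caveat: with zero-mean random intercepts, a constant shift
added to every participant's level cannot stay entirely out of the fixed
surface — shrinkage pushes part of it into the coefficients (this is true
of REML as well, since the model has no free additive offset outside the
load multiplier). The tests therefore assert the property that does hold:
the fit quality is preserved and fitted values track the shift.

Cross-validation is grouped at the participant level: a sex-stratified
k-fold split deals each sex cyclically over folds ordered by occupancy
(so per-sex fold counts differ by at most one, and 30 participants with 3
women at k=3 yield exactly 1 woman + 9 men per fold), each fold's model is
fit on the other folds only, and holdout predictions are scored with the
full validation report. Subject-level separation is asserted, not assumed.

## Validation statistics

- **Bias**: the mean of paired differences (predicted − measured) from a
  random-intercept model — variance components by the one-way ANOVA method
  of moments, then exact GLS weighting of participant means with weights
  `nᵢ/(nᵢτ² + σ²)`. Closed-form, so tests can check it against a
  hand-computed oracle. Reported alongside the descriptive SD of pooled
  differences.
- **Interval**: cluster percentile bootstrap — participants resampled with
  replacement, statistic recomputed per replicate, 5th/95th percentiles
  for a 90% interval. Deterministic given a seed.
- **Equivalence (TOST)**: two one-sided t-tests of the participant-level
  mean differences against ±δ, δ = 10% of mean measured Ṁ by default.
  Degrees of freedom count participants, not observations — many trials on
  few people must not fabricate precision. The report's pass verdict
  applies the stated CI criterion using the bootstrap 90% interval (the
  interval the procedure itself computes); the standalone function uses
  the classical t-based CI, equivalent to both one-sided tests at α.
- **Agreement**: Lin's concordance correlation on pooled pairs with
  population (1/n) moments; a participant-mean variant is available.
- **Outliers**: MAD screen flagging values beyond `cutoff × 1.4826 × MAD`
  from the median (default cutoff 3.0, configurable to 2.5); returns a
  mask and never mutates data.

## Synthetic studies

The generator emulates the study design the model class was developed on:

- **Cohort**: 30 participants (3 women) with truncated-normal
  anthropometrics — age 25 ± 7 yr, height 1.74 ± 0.07 m (window
  1.57–1.90), body mass 77 ± 15 kg (window 48–120), body fat
  21.4 ± 5.0%; lean mass derived as `body_mass·(1 − body_fat)`. Sex is a
  label used for stratification only — the metabolic model has no sex
  term, mirroring the model class itself.
- **Protocol**: per load (0/22/44/66% body mass) one standing trial plus
  walking at 0.45/0.89/1.34 m·s⁻¹ and an individual top speed drawn from
  the load-specific observed distribution (means 1.96/1.86/1.67/1.48,
  SDs 0.04/0.12/0.16/0.12 m·s⁻¹), truncated at ±2 SD, floored to the
  incremental grid 1.16 + 0.09·j, capped at 1.97, and non-increasing in
  load within a participant. 30 × 4 × 5 = 600 trials per study.
- **Noise**: residual SD 0.45 and intercept SD 0.35 W·kg⁻¹, chosen so the
  pooled prediction-error SD (≈ √(0.45² + 0.35²) ≈ 0.57) sits near the
  ~0.6 W·kg⁻¹ spread typical of measured-vs-modelled comparisons in this
  domain. This is a calibration choice, configurable, not a claim about
  any particular dataset. Rates are truncated positive by redrawing the
  residual.
- **Gas traces** (optional): each trial's V̇O₂/V̇CO₂ are back-computed by
  exactly inverting the calorimetry equation at an RER sampled uniformly
  in [0.80, 0.95], then split into two 30-s windows with ≤2% jitter — by
  construction every emitted window passes the steady-state QC screen and
  round-trips to the stored rate.

What the generator does *not* emulate: V̇O₂ drift and slow-component
kinetics, thermoregulatory load, fatigue, incremental-test termination
dynamics, or any sex/body-composition effect on walking cost. Passing
parameter-recovery tests therefore demonstrates that the estimation
machinery is correct and unbiased *under the stated noise model* — not
that the published coefficients are correct for real humans, which only
the original measurements can establish.

## Problem sizes and tolerances

Chosen as the package's own desk-scale defaults: coefficient recovery uses
20 replicate studies (600 trials each) with starting values perturbed
±50% uniformly; the bootstrap coverage check uses 500 simulated datasets
of 30 participants × 4 observations with 400 bootstrap draws; the TOST
power check uses 500 datasets of 30 participants × 17 pairs. Outer fit
tolerance 1e-8 relative on the objective; solver tolerances 1e-12. The
acceptance script derives independent replicate seeds from its master seed
via numpy's `SeedSequence`.

## Known limitations

- The comparator formulas (Pandolf; minimum-mechanics linear-mass model)
  are transcriptions pinned by hand-computed unit tests; the
  minimum-mechanics comparator applies a published gross level-walking
  cost per kilogram of supported mass to body + load, which is the model's
  stated premise, but users comparing against a specific original
  implementation should verify coefficients against that source.
- The grade term is a modular add-on developed on unloaded walking; its
  interaction with heavy loads is untested territory and the package only
  warns, it cannot validate.
- The profiled fitting scheme assumes independent residuals within
  participants; autocorrelated drift within a visit would be attributed to
  the residual component.
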