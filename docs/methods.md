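# Methods

## Scope and estimands

The package estimates 5-year age-standardized net survival for female
cancer-registry cohorts under interchangeable background-mortality life
tables, and quantifies how the life-table construction itself perturbs the
estimate.  The estimand at every stage is the ICSS-standardized Pohar Perme
net survival at five years since diagnosis.

## Life tables

A period life table holds, per single age x, the central death rate `mx`,
the probability `qx` of dying between exact ages x and x+1, survivorship
`lx` (radix 1.0) and the death distribution `dx = lx·qx`.  `qx` is the only
column the survival machinery consumes.  Internally `qx` is authoritative:
tables read from disk are rebuilt from `qx` so the identities
(`lx` non-increasing, `dx` summing with the surviving tail to 1) hold
exactly regardless of on-disk rounding.  The radix-100 000 HMD 1×1 layout is
used only at I/O, with the terminal age marked `+`.

**Exponential conversion.**  `qx = 1 − exp(−mx)` assumes a constant death
rate within each one-year interval.  It is applied both to observed
(unsmoothed) rates and to model-fitted rates.

**Pooling.**  Death counts and exposures are pooled over the three calendar
years centered on the target year before smoothing, to damp year-to-year
fluctuation; the window is fixed at three years.

**Spline smoothing (multivariable flexible model).**  Deaths at single ages
are modelled as Poisson with log link and `log(person-years)` offset, age
entering through a restricted cubic spline: k knots give k−1 non-intercept
columns (Harrell's truncated-power parameterization, normalized by the
squared knot span), twice continuously differentiable at the knots and
linear beyond the boundary knots.  Default knots for women are ages
0, 1, 2, 10, 20, 35, 50, 95 — dense in early life where mortality falls by
orders of magnitude, one knot at 50 where fluctuations flatten, one near the
old-age mass; the classic male set (0, 1, 2, 14, 15, 27, 50, 88) ships as a
named alternative.  The basis parameterization is internal: predictions are
invariant to it, and that invariance — not the coefficients — is the tested
contract.  Fitting is by statsmodels GLM/IRLS; non-convergence raises with
iteration diagnostics rather than returning a half-fitted table.

**Relational systems.**  The Brass model regresses the half-logit
`Y(l) = ½·ln((1−l)/l)` of an observed survivorship schedule on a standard's:
`Y_obs = α + β·Y_std`, α the level of mortality, β the slope of the
relationship, estimated by OLS over ages 1–99 (age 0 is excluded: infant
mortality does not follow the log-linear relation).  The Ewbank system
generalizes the logit to a Box–Cox power transform of the survival odds
`r = (1−l)/l`:

    Y_c(l) = (r^c − 1)/(2c),    c = κ for l > ½,  c = λ for l ≤ ½,

which tends to the Brass logit as c → 0 and vanishes at l = ½ for every c.
Branching is by survivorship value, not literally by age: the survivorship
of a life table crosses ½ at the median age of its death distribution, so
"κ for younger ages, λ for older ages, separated by the median age" is the
same rule — but value-branching keeps the transform continuous at the
boundary, where an age-based rule introduces a spurious jump.  The inverse
is closed-form, `l = 1/(1 + (1+2cY)^{1/c})`, defined while `1 + 2cY > 0`;
strongly negative exponents can make the oldest ages uninvertible, which is
raised as an explicit inversion error (and flagged, not fatal, inside
parameter sweeps).  Smoothing maps the standard through `α + β·Y`, inverts,
and differences the resulting survivorship back into `qx`; the terminal
`qx` is carried over from the standard, whose open-ended interval sits
outside the relational system.  With α=0, β=1, κ=λ=0 the standard is
reproduced exactly (tested to 1e-10).

A profile least-squares fitter over a (κ, λ) grid with α, β re-estimated
per point is provided as an extension for users who want to *estimate* the
shape exponents rather than sweep them.

## Cohorts and exclusions

A record is one registry case: diagnosis date, age at diagnosis (day
precision), vital status at cutoff, death/cutoff date, site, DCO flag.
Exclusions mirror registry practice: death before diagnosis (negative
survival time), death-certificate-only cases (no usable survival time), and
— when the life tables stop at age 99 — patients who would turn 100 within
the follow-up horizon, since their expected hazard would be undefined.
Each reason is counted in a run log.

## Expected hazards and the Pohar Perme estimator

The population hazard of patient i is piecewise constant at
`h = −ln(1−qx[a])`, with a read from the life table of the calendar year
currently traversed at the attained (integer) age; the cumulative hazard
`Λ_Pi(t)` integrates in closed form across birthday and January-1
crossings (time in years of 365.25 days).  Years beyond the last available
table reuse the last table.

The estimator weights each patient by the inverse of their expected
survival, `w_i(t) = exp(Λ_Pi(t))`, and accumulates excess-hazard increments
on a time grid containing every exit day plus regular steps
(`step_days`, default 1):

    dΛ̂_E = [Σ_{deaths} w_i − Σ_{at risk} w_i·dΛ_Pi] / Σ_{at risk} w_i

with weights evaluated at the right endpoint of each step and `dΛ_Pi` exact
over the step.  The curve is the product-limit `NS(t) = Π (1 − dΛ̂_E)`; in
the zero-population-hazard limit every weight is 1 and the estimator
*equals* Kaplan–Meier at event times (the exp-of-cumulative form cannot do
this exactly, which is why the product form is used).  Variance follows the
Poisson-type form `Σ w_i² dN_i / (Σ w_i Y_i)²`, cumulated and scaled by
`NS²`; confidence intervals are plain (identity-scale) normal, the same
convention as the binomial intervals used for overall survival.  Estimates
above 1 are possible (observed mortality below population mortality) and
are reported unclipped with a flag.  Same-day outcomes count at day 1; tied
events are processed simultaneously; the curve truncates with a warning if
the risk set empties before the horizon.

`step_days` is a precision/speed dial: daily steps are effectively exact;
weekly steps change 5-year estimates by well under 1e-3 and are used for
the 200-replicate coverage experiment so it runs in tens of seconds.

**Overall survival** is the complement of the death proportion within the
horizon, with a binomial normal CI; it requires complete follow-up (every
record dead or followed past the horizon), which registries with national
death linkage provide.

**Standardization** uses the ICSS age groups 15–44, 45–54, 55–64, 65–74,
75+ with the standard weight sets (breast/ovary 0.07/0.12/0.23/0.29/0.29;
cervix 0.28/0.17/0.21/0.20/0.14); groups are assigned by age at diagnosis,
patients under 15 fall outside the standard.  The standardized estimate is
the weighted sum, its variance the squared-weighted sum.

## Sensitivity sweeps

One shape exponent is swept (κ over [0, 0.07] step 0.005 with λ = 0.4;
λ over [−0.5, 0.5] step 0.05 with κ = 0.05), rebuilding the relational life
table and re-estimating standardized NS(5) at each grid point.  α and β
stay fixed across the grid — by default at values from a one-time Brass fit
of the unsmoothed observed schedule on the standard; passing the observed
table instead re-fits α, β at every grid point.  The sweep is deterministic
given its inputs.  Grid points whose table cannot be inverted are flagged
and skipped.  Parameter bounds are the linear interpolations of the curve's
crossings with reference survivals computed under other life tables;
non-monotone curves warn and use the first crossing.

On the packaged synthetic world the κ response is strictly monotone but
small, while λ moves the estimate far more: κ deforms the transform in
proportion to (logit l)²/4, which is sizeable only where survivorship is
near 1 — ages whose background mortality contributes almost nothing to a
cancer cohort's expected hazard — whereas λ acts directly on the
high-mortality old tail.  Cohorts whose age structure concentrates below
the split age and whose standard has a very high median death age shift
this balance toward κ; the package reports both spans and their ratio
rather than assuming either regime.  The sign of the κ response is a
convention of the transform's direction; under this parameterization NS
decreases as κ grows.

## Synthetic registry

The generator supplies the statistical structure the analysis assumes, with
analytic truth:

* **Mortality laws** are Siler-type, hazard
  `a + b·exp(c·age) + a_inf·exp(−b_inf·age)`.  The observed-population
  default (a=2.5e-4, b=5.7e-6, c=0.115, a_inf=8e-3, b_inf=1.4) has infant
  `q0 ≈ 0.0046` and median age of death ≈ 82; the relational standard
  (1.2e-4, 8.7e-6, 0.105, 5.5e-3, 1.6) is lighter, median ≈ 85 — the
  level/slope/shape contrast between a heavier and a lighter European
  female schedule that relational fitting presumes.  The infant component
  matters: without it the young-age profile is featureless and both the
  early-life spline knots and the relational systems' young-age branch have
  nothing realistic to work on.  Exact tables use
  `qx = 1 − exp(−∫ hazard)`; noisy tables draw deaths Poisson(rate·exposure)
  per age (default exposure 50 000, a realistic single-age female
  population for a mid-size country).
* **Cohorts** draw, per ICSS group, ages at diagnosis (uniform within
  closed groups; truncated-exponential with 4.5-year scale, capped at 94,
  in the open 75+ group — registry age profiles fall steeply past 80, and
  the cap keeps the age-100 exclusion from interacting with recovery
  tests), diagnosis dates uniform over 2010–2014, and death times from
  total hazard = population + constant group excess, censored at the end of
  2019.  Constant excess gives closed-form truth
  `NS_true(t) = exp(−excess·t)` per group and an analytic standardized
  truth.  Death times under a law invert the cumulative hazard in closed
  form via the Wright omega function (the infant term is negligible at
  entry ages 15+ and is excluded from the inversion by a guard); under a
  life-table series they invert the piecewise-linear cumulative hazard,
  with ages past the table limit reusing the terminal hazard (relevant only
  past the analysis horizon).  Everything is deterministic given the seed.
* The default cohort profile is breast-like: group shares ≈
  10/16/29/24/21% and 5-year net survival declining 0.90 → 0.60 across the
  groups.

What the generator does *not* emulate: site mix and registration-quality
profiles (DCO and verification rates appear only as flags to exercise the
exclusion rules), non-constant excess hazards (a piecewise option exists
but constant is the default for analytic truth), within-year seasonality of
mortality, and calendar trends in background mortality (the table series
used in tests repeats one period table).  Passing tests therefore
demonstrate correctness of the estimators and constructions under the
stated model, not the magnitude of any real population's life-table
effects.

## Numerical choices and problem sizes

* Time unit: 365.25-day years; follow-up in integer days.
* The recovery experiments use n = 5000 cohorts (single run at daily
  precision; 200-replicate CI coverage at weekly precision), chosen so the
  whole suite and the acceptance script each run in about a minute.
* Spline-recovery checks use a pure Gompertz law (log-linear rates, the
  regime the model is designed to smooth) with exposure 10⁶ per age.
* Tolerances: exact identities at 1e-10…1e-12; estimator-vs-oracle at 1e-6;
  stochastic recoveries at 3 standard errors; CI coverage within
  [0.92, 0.98] over 200 replicates.

## Known limitations

* The Ewbank transform's exact historical normalization is not printed in
  the registry literature this package follows; the implementation pins the
  reducibility-to-Brass limit and the l = ½ fixed point, which any
  normalization must satisfy, and documents its convention.
* Life tables are period tables applied per calendar year; no cohort
  (generation) tables, no abridged tables, no ax-based refinements.
* Net-survival CIs use the identity-scale normal approximation; log or
  log(−log) transforms would behave better very near 0 or 1.
* Ederer/Hakulinen relative-survival ratios, cause-specific survival,
  period analysis and cure models are out of scope.
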