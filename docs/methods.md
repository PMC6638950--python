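# Methods

## Scientific setting

Longitudinal pediatric cohorts measure growth at scheduled visits.
Growth retardation (underweight, stunting, wasting) is defined per visit
from WHO-style z-scores; children move back and forth between healthy
and malnourished states and may die, and the data carry three
complications that the standard Cox-on-first-event analysis ignores:
the malnutrition state is only observed at visits (interval censoring),
death competes with malnutrition and removes children informatively,
and attendance itself plausibly depends on the unobserved growth status
(missing not at random). The package combines four pieces to address
these: LMS z-scoring, an interval-censored three-state Markov model,
multiple imputation for covariates, and a two-stage Heckman GEE
correction for outcome missingness.

## Anthropometry

The LMS method maps a measurement `y` to
`z = ((y/M)^L − 1)/(L·S)` for `|L| > 1e-8` and `z = ln(y/M)/S`
otherwise; the threshold is purely numerical (the two branches agree to
~1e-6 at `|L| = 1e-8`, and realistic reference tables keep `|L|`
well above it). Weight-based indices (waz, wlz) are linearised beyond
±3 SD following the WHO convention: beyond the +3 anchor,
`z = 3 + (y − sd3pos)/(sd3pos − sd2pos)` (mirrored below −3), which is
continuous and piecewise linear in `y`; the height-based index (laz) is
not restricted. Whether the original analyses used the restricted tails
is not documented in most cohort reports; the WHO software does, so
restriction is the default and a flag turns it off.

Conventions: age keys are completed months (floor); weight-for-length
keys snap to the 0.1 cm reference grid. A visit classifies as
malnourished when z < −2 *strictly* (a tie at exactly −2 is healthy,
matching the "< −2" definition). |z| > 6 is flagged as implausible
(WHO cleaning convention) but retained; exclusion is the caller's
choice, because no cleaning rule is universal.

The built-in reference table is **synthetic**: smooth L/M/S curves that
track the broad shape of early-childhood growth. Its SD bounds are
derived exactly from (L, M, S), so the table is self-consistent by
construction. Any real WHO CSV export with the same schema
(`index,sex,key,L,M,S,sd3neg,sd2neg,sd2pos,sd3pos`) drops in.

## The three-state model

States 1 = healthy, 2 = malnourished, 3 = dead (absorbing); transitions
1→2, 1→3, 2→1, 2→3. Time is age in months with t = 0 at birth.
Intensities are piecewise constant on the bands (0,6], (6,12], (12,60]
— the cut points at which band-specific incidence is conventionally
reported for this age range — with shared-across-bands proportional
covariate effects, `q_rs(t, x) = q0_rs(band(t)) exp(β_rs·x)`. Covariate
effects shared across bands is a deliberate choice: reports print one
adjusted hazard ratio per covariate per transition.

The likelihood uses the mixed observation scheme: a panel pair (state r
at t1, state s at t2) contributes `P_rs(t1, t2)`, computed as the
ordered product of band-wise matrix exponentials; an exactly observed
death contributes `Σ_{k∈{1,2}} P_rk(t1, t2) q_k3(t2)` because the live
state just before death is unknown. Time-dependent covariates are held
at their last observed value over each interval (the standard
panel-data approximation). Children enter the likelihood at their first
visit with a non-missing state; the likelihood conditions on that first
state.

Implementation notes:

* The death column of the generator is structurally zero, so the live
  block is 2×2 and its matrix exponential has a closed eigenvalue form
  (real eigenvalues are guaranteed for this sign pattern); the
  likelihood evaluates it vectorised over all distinct
  (interval, state-pair, covariate-pattern) cells, which fixed visit
  grids collapse to a few hundred. The public
  `transition_probability` uses the generic scipy expm; tests check the
  two routes against each other and against an ODE integrator.
* Initialisation: crude occurrence/exposure rates floored at 1e-4 per
  month; covariate effects start at 0. Optimisation: BFGS with
  numerical gradients, with a Nelder-Mead polish only if BFGS reports
  failure.
* Transitions never observed in the data are fixed at intensity zero
  and excluded from estimation. A *band* with zero observed events
  drives its log-intensity towards −∞ on a flat likelihood; such
  directions are detected by their vanishing curvature and reported
  with infinite log-scale variance rather than a failed covariance.
* Covariance is the inverse observed information from a central finite-
  difference Hessian (relative step 1e-4). Intensity confidence
  intervals are formed on the log scale (guaranteeing positive bounds
  and the familiar asymmetric intervals); hazard-ratio intervals are
  `exp(β ± 1.96 SE)`.
* A zero-probability observed transition yields log-likelihood −inf
  (with a diagnostic naming the offending interval), never an
  exception, so optimizers can recover.

## Missing covariates

Chained equations: each incomplete variable is regressed on all other
model variables, with posterior-draw imputation — Bayesian linear
regression for continuous variables (σ² from a scaled inverse-χ², β
from its normal posterior), logistic for binaries with an approximate
normal posterior draw of the coefficients, multinomial sampling for
unordered categoricals. Defaults are 10 imputations × 10 iterations
(the convention for moderate ~10% missingness); predictive mean
matching is available for continuous variables. Anthropometric outcome
columns are excluded from the imputation model — their missingness is
the selection model's job, and MAR imputation of the outcome would
contradict the MNAR analysis.

Rubin's rules pool per-parameter estimates on the estimation scale
(log-intensities and β, not hazard ratios — the rules assume
approximate normality): `T = W + (1 + 1/m)B` with the standard
small-sample degrees of freedom. The pooled likelihood-ratio statistic
(D3) averages per-imputation LR statistics at their own MLEs (`d̄_m`)
and re-evaluated at the across-imputation mean parameters (`d̄_L`);
`r_L = (m+1)/(k(m−1)) (d̄_m − d̄_L)` clipped at zero (negative values
are sampling noise and are logged), `D3 = d̄_L/(k(1+r_L))` against
F(k, ν) with the published denominator-df rule (for k(m−1) ≤ 4 the
small-sample branch uses k(m−1)(1+1/k)(1+1/r_L)²/2). Re-evaluating
likelihoods at pooled parameters requires the multi-state likelihood to
be callable at arbitrary parameter values on each completed dataset;
`MarkovMultiState.loglik(theta, data)` is that contract.

## Selection correction for outcome missingness

Stage 1 is a GEE probit (clustered on child) for the indicator "growth
outcome observed at the scheduled visit", on baseline and
time-dependent covariates. The inverse Mills ratio λ = φ(η̂)/Φ(η̂) at
each observed record's linear predictor is the standard two-step
construction: under a bivariate-normal selection model,
E[outcome error | selected] ∝ λ(η̂). It is evaluated as
`exp(logpdf − logcdf)`, stable to η = −40 and beyond (λ ≈ −η + 1/η in
the deep left tail); λ underflows to exactly zero only past η ≈ +37.6
where φ leaves the double range. Stage 2 is an identity-link GEE with
exchangeable working correlation for the marginal z trajectory — age
enters as age + age² (age in years) — fit with and without λ; the
difference between the two tables is the package's sensitivity
analysis for the missingness mechanism.

Because λ is a generated regressor, analytic stage-2 standard errors
are invalid; a cluster bootstrap (children resampled with replacement,
duplicated children given fresh ids, both stages re-run per replicate,
default 500 replicates) provides percentile intervals and symmetry
p-values (2·min(frac ≤ 0, frac ≥ 0); a normal-approximation p is an
option). Replicate failures are logged and excluded, with an error if
more than 5% fail. An exclusion restriction (a stage-1 covariate absent
from stage 2 — site, in the synthetic analyses) is recommended and its
absence warned about, since identification otherwise rests on the
probit nonlinearity alone.

## The synthetic cohort generator

The generator emulates the study conditions of a four-group
HIV-exposure cohort: group sizes (69, 141, 205, 196) for
(HI, HIL, HEU, HUU); visits every 3 months to 24 months then every 6
months to 60 for the infected groups and every 6 months for the
uninfected groups; baseline intensities (per month) at the published
per-1000-person-month scale — healthy→malnourished (.0372, .0116,
.0068), healthy→death (.0096, .0201, .0003), malnourished→death
(.0353, .0840, .0060) across the three bands. The malnourished→healthy
recovery intensities are not published; (0.15, 0.10, 0.05) per month
were chosen once as a realistic recovery profile (median time to
recovery of a few months, slowing with age) and give malnourished-state
prevalences in the plausible range. Child-level covariates are drawn
with group-dependent marginal frequencies in the range of the cohort's
descriptive table; time-varying clinical covariates (chronic pathology,
diarrhea, CD4 < 25%, anemia, systemic signs) are refreshed per visit.

Two modes serve different tests. `state_first` draws the
continuous-time Markov path directly (band-boundary crossings re-draw
the sojourn, valid by memorylessness) and reads visit states off the
path, with exact death times — the inverse of the fitted model, for
parameter recovery. `trajectory_first` draws latent z trajectories
(quadratic in age-in-years with coefficients 0.84 and −0.16, group
offsets −0.35/−0.55/0/+0.25 for HI/HIL/HEU/HUU, child random intercept
SD 0.9, visit noise SD 0.6) and produces raw weight/length through the
inverse LMS transform; deaths in this mode use the healthy→death band
rates only, a simplification adequate for its purpose (selection-model
experiments).

Dropout is MCAR, MAR (site only) or MNAR — probit on the *current,
possibly unobserved* z with loading −0.7 plus site effects, so low
z-scores go missing more often and the observed-data mean is biased
upward; the baseline visit is always observed. Covariate missingness is
MAR given group and site at ~10%. Random streams are split per child
id, so subsetting a cohort leaves retained children's data unchanged.

What the generator does **not** emulate: measurement error in
anthropometry, seasonal effects, informative visit timing (visits
happen exactly on the grid or not at all), within-child correlation
between the three indices beyond a shared random intercept, and
covariate-dependent death beyond the configured hazard multipliers.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated model, not robustness to these real-data
features.

## Problem sizes in the replicated experiments

The Wald-coverage experiment uses 200 replicate cohorts of 2,000
children (all four transitions, no covariates) and checks that each of
the 12 log-intensity 95% intervals covers its generating value in
90–98% of fits. The selection-bias experiment uses 200 replicate MNAR
cohorts of 600 children and compares the absolute median bias of the
corrected and naive group-effect estimates; the bootstrap does not
enter point estimates and is skipped there, while bootstrap determinism
and calibration are tested separately. The stage-1 probit in the
replicated experiments uses an independence working structure (an
exposed option; single analyses default to exchangeable).

## Known limitations

* No hidden-Markov (misclassification) layer, semi-Markov sojourns or
  frailty terms; band-specific covariate effects are not estimated.
* Full-information maximum-likelihood Heckman (joint bivariate normal)
  is out of scope; the two-step estimator is less efficient but more
  robust to the joint-normality assumption.
* The chained-equations imputer assumes MAR given the included
  variables and uses approximate posterior draws for the
  binary/categorical conditionals.
* The three indices are analysed as three independent pipelines; a
  joint indicator across indices is not modelled.
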