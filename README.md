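# growthmsm

Statistical machinery for studying **growth retardation in pediatric
cohorts**: WHO-style LMS z-scores, a three-state interval-censored Markov
model for the dynamics of malnutrition and death, multiple imputation
with Rubin and Meng–Rubin pooling, and a two-stage Heckman GEE correction
for informative missingness of growth outcomes. It is aimed at
biostatisticians analysing longitudinal child-growth cohorts — visit
schedules fixed a priori, states observed only at visits, death competing
with malnutrition, and dropout plausibly driven by the unobserved growth
status itself.

## The models

**Anthropometry.** Raw weight/length map to z-scores through the LMS
method: `z = ((y/M)^L − 1)/(L·S)` (log branch at `L = 0`), with the WHO
convention of linearising the weight-based indices beyond ±3 SD. A visit
is *malnourished* when the index z-score is strictly below −2, giving the
state space 1 = healthy, 2 = malnourished, 3 = dead.

**Multi-state model.** Transitions 1→2, 1→3, 2→1, 2→3 have
piecewise-constant baseline intensities on age bands (0,6], (6,12],
(12,60] months with proportional covariate effects,
`q_rs(t, x) = q0_rs(band(t)) · exp(β_rs·x)`. Live states are
interval-censored (panel observation), deaths are observed exactly with
unknown state just before death, so a death at `t2` contributes
`Σ_k P_rk(t1, t2) q_k3(t2)` to the likelihood. Estimation is by
quasi-Newton maximum likelihood with the observed-information covariance;
results are reported as adjusted hazard ratios `exp(β)` and intensities
per 1000 person-months with log-scale Wald intervals.

**Missing covariates.** Chained-equations multiple imputation (Bayesian
linear, logistic, multinomial conditionals), Rubin's rules
`T = W + (1 + 1/m)B`, and the Meng–Rubin pooled likelihood-ratio
statistic `D3` for variable selection across imputations.

**Informative outcome missingness.** A GEE probit on the per-visit
"outcome observed" indicator gives a linear predictor `η̂`; the inverse
Mills ratio `λ = φ(η̂)/Φ(η̂)` enters the identity-link GEE for the
marginal z trajectory as an extra covariate, and a cluster bootstrap
(children resampled with replacement, both stages re-run) provides valid
inference for the generated regressor.

A synthetic-cohort generator with known ground truth (four exposure
groups, fixed visit grids, band-wise intensities at the published scale,
MNAR dropout loading on the current z-score) makes every stage testable
by parameter recovery.

## Worked example

```python
import numpy as np
from growthmsm import (CohortConfig, MarkovMultiState, panel_from_cohort,
                       simulate_cohort)
from growthmsm.synthetic import DropoutModel

cfg = CohortConfig(seed=1, group_sizes=(500, 500, 500, 500),
                   dropout=DropoutModel(mode="MCAR", rate=0.0))
cohort = simulate_cohort(cfg, mode="state_first")
est = MarkovMultiState().fit(panel_from_cohort(cohort))
tab = est.intensity_summary()
print(tab[tab.transition == "1->2"][["band", "per1000pm", "lower", "upper"]])
```

prints (seed 1):

```
      band  per1000pm      lower      upper
0    (0,6]  35.503226  29.705567  42.432421
1   (6,12]  14.314852  11.449184  17.897780
2  (12,60]   7.079714   6.411673   7.817359
```

i.e. the healthy→malnourished intensity per 1000 person-months per age
band, re-estimated from interval-censored visit data; the generating
values were 37.2, 11.6 and 6.8. `est.hazard_ratios()` reports covariate
effects the same way, and `growthmsm.pipeline` chains classification,
imputation, pooled fitting and the Heckman arm behind one config.

A CLI mirrors the library: `growthmsm simulate|zscore|msm|heckman|
describe|report` (all outputs deterministic given `--seed`).

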