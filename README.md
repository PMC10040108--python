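# curecorrect

Mixture cure survival models for population-based cancer data, with a
multiplicative correction for **excess non-cancer mortality**.

## The problem

Cancer patients often die of causes other than their cancer at a higher
rate than age- and sex-matched members of the general population
(late treatment effects, shared risk factors, second cancers).
Conventional relative-survival and cure-model analyses assume the
patients' other-cause mortality equals the general-population mortality
taken from life tables; when that assumption fails, net survival and
cure fractions are systematically underestimated. This package is for
biostatisticians and cancer-registry epidemiologists who want cure-model
indicators that remain valid under such excess mortality.

## The model

Net survival is modelled as a two-component mixture with cure fraction
π and Weibull net survival of the uncured:

    RS(t | x) = π(x) + (1 − π(x)) · S_u(t, x)
    π(x)      = [1 + exp(−β₀ − β x)]⁻¹          (logistic link; identity optional)
    S_u(t, x) = exp(−λ tᵞ) ^ exp(−δ x)

with standardized age x = (age − 60)/15. The corrected model multiplies
the expected (general-population) hazard h\*(age + t) by a factor α > 0,
so the observed survival factorises as

    S_O(t) = RS(t | x) · S*(t | age)^α .

α is a hazard ratio: α > 1 means the cohort's non-cancer mortality
exceeds the general population's; α = 1 recovers the conventional
mixture cure model exactly. Parameters (α, π₆₀, λ, γ, β, δ) are
estimated by maximum likelihood either from individual records
(observed-hazard likelihood) or from grouped life tables (binomial
likelihood per stratum × annual interval, with Ederer II expected
interval survival), with Wald intervals on transformed scales.

The package also ships the full simulation machinery used to validate
the estimator: virtual cohorts with inverse-transform sampling of
non-cancer death times from S\*^α, mixture sampling of cancer death
times, administrative/loss-to-follow-up censoring, and three
single-assumption robustness violations (exponentiated-Weibull uncured
survival, age-linear α, patient-level random α), plus replicate
experiments summarised by absolute bias, between-replicate standard
deviation, and 95%-interval coverage.

## Worked example

```python
from curecorrect import (PopulationMortality, breast_scenario,
                         build_life_table, generate_cohort, MixtureCureModel)

pop = PopulationMortality.weibull()          # scale 88 y, shape 11
cfg = breast_scenario(alpha=1.2, n=10_000, seed=42)
cohort = generate_cohort(cfg)
table = build_life_table(cohort, pop=pop)    # 4 age strata x 15 annual intervals
res = MixtureCureModel(table, variant="corrected").fit()
print(res.summary())
```

```
Mixture cure model (corrected)
  variant: corrected   link: logistic   data: grouped
  n cells: 60   log-likelihood: -14944.9920   converged: True

  param     estimate        se                95% CI
  alpha       1.1068    0.0884   [0.9465, 1.2943]
  pi_60       0.6967    0.0355   [0.6231, 0.7614]
  lambda      0.1039    0.0106   [0.0850, 0.1269]
  gamma       1.0963    0.0437   [1.0140, 1.1853]
  beta       -0.3218    0.2002   [-0.7142, 0.0707]
  delta       0.2182    0.1444   [-0.0648, 0.5012]
```

The cohort was generated with α = 1.2 and a 70% cure fraction at age
60; the fit recovers α̂ = 1.11 (95% CI 0.95–1.29) and π̂₆₀ = 0.70.
`res.predict_summary()` then tabulates net survival by age and horizon:

```
    age     pi  ns_1y  ns_5y  ns_10y  ns_15y
0  40.0  0.779  0.971  0.877   0.818   0.794
1  60.0  0.697  0.970  0.862   0.780   0.737
2  70.0  0.650  0.970  0.857   0.764   0.711
```

Each row gives the estimated cure fraction and net survival at 1, 5, 10
and 15 years for one age at diagnosis.

A `curecorrect` console command wraps the same pipeline
(`simulate`, `lifetable`, `fit`, `experiment`, `predict`); see
`curecorrect --help`.

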