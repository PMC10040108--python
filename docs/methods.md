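# Methods

## Model

The package implements mixture cure models in the relative-survival
setting. A cohort's observed all-cause hazard is split into a
cancer-attributable (excess) hazard `h_c` and an other-cause hazard
`h_e`. The conventional assumption `h_e(t) = h*(age + t)` — the
general-population hazard from a life table — is relaxed to

    h_e(t) = α · h*(age + t),        α > 0,

so observed survival factorises as `S_O(t) = RS(t) · S*(t | age)^α`,
where `RS` is net survival and `S*(t | age)` the conditional
general-population survival from age at diagnosis. α acts as a
hazard ratio for non-cancer death: α > 1 means excess other-cause
mortality in the cohort, α = 1 reduces the model exactly to the
conventional one.

Net survival is a two-component mixture: a cured fraction `π(x)`
(logistic in standardized age x = (age − 60)/15 by default; an identity
link is available and is validated rather than clamped, so a fitted
identity-link π outside [0, 1] fails loudly) and Weibull net survival
of the uncured, `S_u(t, x) = exp(−λ tᵞ)^exp(−δx)`. A third variant
keeps α free but drops the cured component (π ≡ 0), useful as a
comparison when the estimated cure fraction is very small.

Key assumptions: α is a fixed effect, constant in age and across
patients; uncured net survival is Weibull; the cure fraction follows
the link model in age; expected mortality is exchangeable with the
cohort apart from the factor α. The simulator's robustness settings
violate each of the last three deliberately (see below).

### Age-effect convention

One sign convention is used everywhere, in the estimator and in the
generator alike: the age effect on uncured survival enters as the
survival exponent `exp(−δx)` (equivalently a multiplicative effect on
the uncured hazard). Positive δ therefore means *lower* uncured
mortality at older ages; the low-survival preset's δ = −0.3 means
uncured mortality rising with age. Because generation and fitting share
the convention, fitted δ recovers the generating δ directly.

## Parameters

| symbol | meaning | units / scale | preset values |
|---|---|---|---|
| α | excess non-cancer mortality factor | hazard ratio | 0.8–2 across experiments |
| π₆₀ | cure fraction at age 60 | probability | 0.7 ("high survival"), 0.1 ("low survival") |
| β | cure trend per 15 y of age (link scale) | logit / identity | −0.15, −0.75 |
| λ, γ | Weibull rate-scale and shape of uncured net survival | λ in y^−γ | (0.1, 1.1), (0.9, 0.8) |
| δ | uncured-survival age effect per 15 y | survival exponent exp(−δx) | 0, −0.3 |
| λ_P, γ_P | population Weibull scale (years) and shape | S*(a) = exp(−(a/λ_P)^γ_P) | 88, 11 |

The population mortality model is either this parametric Weibull
(conditioned on continuous age at diagnosis — ages are never rounded)
or a tabulated life table with piecewise-constant annual hazards
(`qx` columns converted via `h = −log(1 − qx)`; cumulative hazard
interpolated linearly within years).

## Estimation

**Individual data.** Each record contributes
`d·ln(h_c + α h*) + ln RS + α ln S*`, the standard observed-hazard
log-likelihood. With α = 1 the expected-survival term is a constant; a
flag keeps it so likelihood values stay comparable across variants.
Events recorded at exactly t = 0 are shifted to half a day
(0.5/365.25 y) before evaluation because the Weibull hazard may diverge
at the origin.

**Grouped data.** Cohorts are grouped into life tables (default: the
four age classes 40–57, 58–64, 65–69, 70–74, annual intervals to 15
years). Cell counts follow actuarial conventions: deaths and
censorings assigned to half-open intervals `[t_{j−1}, t_j)`; effective
number at risk `l = n − 0.5w` (censored patients get half-interval
exposure); records censored exactly at the end of follow-up are
survivors of the last interval, not mid-interval censorings. The
Ederer II expected interval survival `s_exp` averages, over patients at
risk at the interval start, their individual conditional population
survivals. Each cell then contributes a binomial term
`d·ln(1 − p) + (l − d)·ln p` with predicted conditional observed
survival

    p_jk = [RS(t_j; x_k) / RS(t_{j−1}; x_k)] · s_exp_jk^α   (default, "exact")

evaluated at the stratum's realized mean standardized age `x_k` (the
mean, not the class midpoint, minimises within-stratum aggregation
bias). An additive first-order dialect
`p = r + α·ln s_exp` is retained as an option; the two agree to better
than 0.01 whenever interval survivals exceed 0.95 and α ≤ 2. Cells
pushed outside (0, 1) during optimisation contribute a smooth penalty
rather than NaN, keeping quasi-Newton steps well-defined.

**Optimisation and uncertainty.** The likelihood is maximised by BFGS
on a working scale (ln α, ln λ, ln γ unconstrained; β₀, β, δ
untransformed), with up to three jittered restarts seeded
deterministically from the data on non-convergence; a fit that still
fails is returned flagged, never raised. Standard errors come from the
inverse numerical Hessian at the optimum; 95% Wald intervals are formed
on the working scale and back-transformed, which keeps intervals for
positive parameters inside the parameter space. π₆₀ and its interval
are the inverse logit of the intercept interval (delta-method SE).
Deterministic starting values come from the life table itself: α = 1;
π₆₀ at the size-weighted last-interval cumulative relative survival
(clamped to [0.05, 0.95]); λ, γ from a least-squares line on the
complementary log-log of the pooled early relative survival; β = δ = 0.

## Simulator

Virtual cohorts reproduce the validation study's conditions: ages drawn
uniformly within four classes of equal 25% weight (continuous within
[lo, hi+1)); administrative censoring uniform on [0, max follow-up]
with probability 0.5 and loss to follow-up with probability 0.03
(minimum of the two, default 15-year horizon); non-cancer death times
by inverse transform from `S*(t | age)^α`; cancer death times by
mixture inversion (cured patients, `u* ≤ π(x)`, get infinite times);
follow-up is the minimum of all candidate times with death winning
ties. One global seed expands into independent per-replicate
substreams, so any replicate is reproducible in isolation and a fixed
seed yields byte-identical cohort CSVs.

Three robustness violations, mutually exclusive by validation:

* **theta** — uncured times from the exponentiated Weibull
  `S_u = {1 − [1 − exp(−λtᵞ)]^θ}^exp(−δx)`; θ = 1 is the null.
* **b_alpha** — age-linear factor `α_x = α + b_α(age − age_center)`,
  rejected if non-positive anywhere in the age range. `age_center`
  defaults to 62.25, the mean of the sampled age distribution as stated
  in the study text; the study's printed α ranges at ages 40/75 are
  consistent with 62.5 instead, so the centre is a config field —
  the induced difference in α_x is at most 0.25·|b_α|.
* **alpha_ratio** — patient-level log-uniform α on `[a, ρa]` with
  `a = α·ln ρ/(ρ − 1)`, which keeps the arithmetic mean at α.

What the generator does **not** emulate: calendar-period trends in
population mortality, sex-specific life tables, non-linear or
non-monotone age effects, dependence between censoring and survival,
and reporting artefacts of real registries (late ascertainment, exact
ties). Passing tests therefore demonstrate correctness of the
estimator under the stated data-generating mechanisms, not performance
on any particular registry's data.

## Performance experiments

`run_replicates` fits R independent cohorts; `performance` summarises
each parameter by absolute bias (mean estimate − truth), SD of the
estimates (denominator R − 1) and coverage of nominal 95% intervals,
over converged replicates only, reporting the non-convergence count.
`scenario_grid`/`run_experiment` emit the full factorial grids
(scenario × α; conventional vs corrected; sample size × follow-up;
θ; b_α; α ratio) with overridable R and cohort size.

The test suite runs the replicate checks at R = 100–300 with N = 10,000
cohorts (grouped fits cost ~50 ms each), comparing against reference
values at Monte-Carlo tolerance 3·SD/√R; the acceptance script runs the
coverage experiment at the full R = 1000.

## Known limitations

* Under strong misspecification the conventional (α ≡ 1) model's
  grouped likelihood degenerates to a near-flat ridge in π₆₀: fitted to
  data generated with α = 2, the likelihood increases monotonically
  (by only a few units) as π₆₀ falls from ≈0.4 toward 0, so the
  maximum-likelihood cure fraction collapses and the reported bias of a
  conventional fit depends on where an optimizer stops along the
  ridge. This package reports the actual likelihood optimum. Under
  mild misspecification (α between 0.8 and 1.2) the ridge is regular
  and conventional-model biases are stable.
* Without a visible cure plateau (cure fraction near zero and γ < 1),
  α is weakly identified from grouped data over a 15-year horizon: the
  no-cure variant then returns very wide α intervals. This is a
  property of the data, surfaced honestly by the SEs.
* Uncured survival is Weibull only; lognormal, loglogistic or spline
  alternatives are out of scope, as are Ederer I / Hakulinen /
  Pohar Perme expected-survival estimators and jackknife variances.
* Wald intervals on transformed scales are asymptotic; at very small
  sample sizes (N ≤ 500, short follow-up) coverage degrades, mirroring
  the instability the validation experiments show there.
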