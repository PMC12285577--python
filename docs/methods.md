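# Methods

`gxlife` implements a gene–lifestyle interaction analysis for obesity on
synthetic cohorts: composite and weighted healthy-lifestyle scoring,
polygenic-score (PGS) stratification, joint and isolated effect estimation
under proportional-hazards and logistic contracts, additive-interaction
decomposition, absolute risk by a target age, and a morbidity scan probing
BMI mediation of the genetic effect. This note records the models, the
defaults and why, the numerical choices, and what the synthetic cohort does
and does not emulate.

## Lifestyle scoring

Five obesogenic behaviors are classified from raw measures into binary
favorable indicators:

| factor | favorable iff | unit |
|---|---|---|
| physical activity | MET minutes/week **> 3000** (strict) | MET·min/wk |
| diet | **≥ 4 of 8** healthy-diet criteria met | count 0–8 |
| sedentary behavior | screen time **≤ 2** h/day | h/day |
| alcohol | **≤ 14** g/day (women), **≤ 28** g/day (men) | g/day |
| sleep | duration in the closed interval **[6, 8]** h/day | h/day |

The composite score is the count of favorable factors (0–5), banded into
*poor* (0–1), *intermediate* (2–3) and *healthy* (4–5). The weighted score
replaces unit points with obesity-association weights `b1..b5` — absolute
values of the favorable-indicator coefficients from one mutually adjusted
logistic regression of prevalent obesity on all five indicators plus
covariates — rescaled by `5 / Σb` so it also spans [0, 5]. Weights are taken
as absolute values because favorable indicators carry negative coefficients
on the obesity scale; a one-factor-at-a-time weighting fit is available as an
option (`mutually_adjusted=False`), mutual adjustment being the default since
the factors are correlated with each other only weakly but all compete for
the same outcome variance. Weighted scores are banded with the same numeric
edges as the integer score, half-open: [0, 2), [2, 4), [4, 5] — a
deterministic tie rule that reproduces the integer banding exactly.
Missing any raw measure gives a missing indicator, a missing score, and
complete-case exclusion downstream. Scores outside [0, 5] are rejected;
float round-off at the 5.0 cap is clipped.

## Genetic risk

Raw per-individual PGS values are standardized to mean 0 / sample SD 1
(ddof = 1). Categories are rank-based: *low* = lowest quintile (empirical
percentile ≤ 20), *high* = top quintile (percentile > 80), *intermediate*
otherwise. Percentiles use the average-rank convention, so a tied block
falls entirely on the side holding its average rank — deterministic and
permutation-invariant, and categories are invariant to affine transforms of
the raw scores. The same machinery produces top-20% flags for the
alternative adiposity indices and the high-PGS carrier contrast.

## Regression contracts

Incident endpoints use Cox proportional-hazards partial likelihood with
**Breslow** tie handling (Efron optional), fitted via `statsmodels.PHReg`;
prevalent endpoints use maximum-likelihood logistic regression
(`statsmodels.Logit`). Wald inference throughout; CIs fixed at 95%;
HR/OR = exp(coef). Two covariate presets exist: `"main"` (enrollment age,
sex, education, deprivation tertile, smoking status, diabetes,
weight-affecting conditions, weight-gain medication; plus genotyping array
and 10 principal components when the PGS enters the model) and
`"risk-curve"` (age, sex, 4 PCs).

Degenerate designs are handled explicitly rather than by failure: constant
columns, and rare binary columns (< 1% of rows and either fewer than five
carriers or carrier events all on one side) whose maximum-(partial-)
likelihood estimates are unbounded or numerically unstable, are pinned at 0
and listed in `FitResult.dropped_constant`. Convergence is verified through
the score norm, not the optimizer's iteration flag.

The joint 3×3 grid fits **one** model with eight joint-category indicators
against the low-genetic-risk / healthy-lifestyle reference cell; empty cells
are flagged non-estimable. Isolated effects adjust one domain's categories
for the other domain plus covariates; trend p-values come from refitting
with the domain's continuous score, exposed as `result.trend_p`.

## Absolute risk by a target age

The timescale is follow-up time with enrollment age as a covariate. The
predicted probability of the endpoint by age `T` (default 75) is

    1 − S0(t*)^exp(η),  t* = T − mean enrollment age,

with S0 the Breslow baseline survival at covariates = 0 (computed directly
from the fitted coefficients, H0(t) = Σ d_j / Σ_{risk} exp(xβ)) and η the
linear predictor at the requested lifestyle group, the standard-normal
quantile of the requested PGS percentile, and covariate means. Since t*
(≈ 20 y) exceeds the administrative follow-up horizon (11.55 y), the
baseline cumulative hazard is extended beyond the last event time at the
average observed baseline rate, H0(t) = H0(t_max)·t/t_max — exact when the
baseline hazard is constant, which is the synthetic generator's regime; for
real data with a non-constant baseline this extension is an explicit
modeling assumption. An age-as-timescale formulation with left truncation
would avoid the extension but changes the estimand; the covariate-based
formulation matches the adjustment lists used everywhere else. The
"median probability" per lifestyle group is the median over the 1–99
PGS-percentile grid (the averaging population is an interpretation choice,
flagged here).

## Interaction

Multiplicative interaction is the Wald test of the PGS × lifestyle product
term in the adjusted logistic model of prevalent obesity (the default
interaction endpoint: genetic influence accumulates from before enrollment,
and restricting to post-enrollment incident cases would understate it).
Additive interaction uses two continuous exposures; relative risks are
approximated by odds ratios (recorded in the output metadata — the
approximation deteriorates as outcome prevalence grows) at four contrast
corners. Default contrast: PGS at the means of the bottom/top quintiles of a
standard normal (∓φ(z₀.₈)/0.2 ≈ ∓1.40) and lifestyle at 0.5 / 4.5
unfavorable points; both configurable. Then

    RERI = RR11 − RR10 − RR01 + 1
    AP_G = (RR10−1)/(RR11−1),  AP_L = (RR01−1)/(RR11−1),  AP_I = RERI/(RR11−1)

and the three AP components sum to 1 identically. RERI is defined for any
positive RRs; the AP decomposition requires RR11 > 1 (no excess joint risk →
explicit error from `decompose`, NaN shares from the fitted front-end).
CIs come from a nonparametric participant-level bootstrap (percentile
method, B = 1000 default, deterministic given a seed, failures on resamples
counted and bounded at 5%); a delta-method CI for RERI is provided as the
lighter alternative. APs are ratios of correlated estimates, hence the
bootstrap default.

A structural point discovered during calibration: with OR-as-RR from a
log-linear model, large main effects make RERI > 0 through curvature alone,
and a *positive* product term is only compatible with a genetic-dominant AP
split (≈57/25/18) when the joint relative risk RR11 is below ≈2.3. The
genetic-dominant calibration (`calibrated_interaction_config`) therefore
solves the liability coefficients exactly for that split at RR11 = 2
(β_pgs = 0.159, β_lifestyle = 0.059, β_interaction = 0.0018 per SD·point).
Because the product coefficient is necessarily tiny, single-cohort AP
estimates at n = 50,000 are noisy (SD up to 0.24); the AP split is therefore
assessed and reported as the Monte-Carlo mean over replicate cohorts, where
the estimator is unbiased and the ordering AP_G > AP_L > AP_I resolves
clearly.

## Morbidity scan and BMI mediation

Each of 20 time-to-event morbidity endpoints is compared between the top
20% of the PGS and the remaining 80% with an adjusted Cox fit; nominal
replication at p < 0.05 and Bonferroni significance at p < 0.05/20 (strict
inequalities). Subgroup contrasts split high-PGS carriers into healthy vs
unfavorable lifestyle (unfavorable = poor ∪ intermediate), each against
everyone outside the subgroup. Mediation is tested by adjustment: refitting
with baseline BMI and reporting the attenuation ratio (adjusted / unadjusted
log-HR). Under the generator's default — genetic effect on morbidities
purely BMI-mediated — adjusted HRs collapse toward 1. "Comparable risk" is
reported as a CI-covers-1 flag, never as acceptance of the null.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes; its
defaults are the study conditions:

* **n** 20,000 (demo default; analyses in tests/acceptance use 50,000).
* **Raw lifestyle measures** drawn from simple parametric families whose
  parameters are inverse-calibrated so the classification rules reproduce
  the target favorable prevalences (0.324, 0.369, 0.673, 0.332, 0.894 for
  activity, diet, alcohol, sedentary, sleep) in expectation: MET minutes
  exponential, diet criteria Binomial(8, q), screen hours Gamma(2, θ),
  alcohol exponential per sex, sleep Normal(7, σ). The raw distributions are
  plumbing; only the classified indicators carry meaning downstream.
  Factors are generated independently (joint dependence is not emulated —
  real lifestyle factors cluster, so real-data composite-score variance
  differs).
* **PGS** standard normal.
* **BMI** = 26.0 + 1.6·PGS + 0.5·(unfavorable count) + N(0, 3.5²) kg/m²,
  giving mean ≈ 27.4 and ≈ 24% of the cohort at BMI ≥ 30. Body fat %, waist
  circumference and waist-to-hip ratio are linear in BMI and sex plus noise.
* **Prevalent obesity** from a logistic liability
  logit p = −2.0 + 0.55·PGS + 0.27·unfav + 0.05·PGS·unfav
  (≈ 22% prevalence; the per-SD and per-point coefficients are set so the
  quintile-category and lifestyle-category odds-ratio contrasts sit near the
  headline set-points; the marginal category OR exceeds exp(0.55·2.8)
  because the product term contributes on average). This liability flag is
  deliberately a *separate* mechanism from the BMI ≥ 30 derivation — the
  endpoints module computes the latter, interaction analyses use the former;
  the two agree in structure but not per-individual.
* **Incident obesity**: exponential baseline hazard 1.4×10⁻³/py at PGS 0 and
  zero unfavorable factors, log-hazards 0.22/SD and 0.11/factor, so the
  population-average rate ≈ 2×10⁻³/py yields ≈ 2.3% cumulative incidence
  over the horizon and the high-vs-low quintile log-HR ≈ 0.62 (HR ≈ 1.86)
  and poor-vs-healthy ≈ ln 1.48. These rates emulate the characteristic
  rarity of diagnosis-coded incident obesity, which sits far below the
  BMI-threshold transition rate because the code is typically assigned to
  severe cases.
* **20 morbidity endpoints**: exponential baselines 3×10⁻³/py; endpoints
  1–15 carry log-hazard 0.08 per kg/m² of BMI above 25 (so the scan should
  replicate 15 of 20), endpoints 16–20 are null; the direct PGS term is 0 by
  default so genetics acts on morbidity only through BMI.
* **Follow-up**: administrative censoring at a fixed 11.55-year horizon (the
  study's median follow-up); death and loss are right-censoring, no
  competing risks. Events are generated for everyone; incident analyses
  exclude the baseline-obese.
* **Missingness**: BMI and outcome fields blanked independently at 0.0032
  and 0.0001 (the enrollment-flow fractions); overlap arises by chance and
  is recorded in provenance metadata.
* **Covariates**: age ~ U(40, 70), 54% female, 10 standard-normal PCs,
  plausible prevalences for education, deprivation, smoking, diabetes,
  weight-affecting conditions and medication. These covariates do **not**
  enter the outcome-generating models — they exist so adjusted fits exercise
  realistic designs; real confounding is therefore not emulated, and a test
  passing under adjustment shows estimator correctness, not confounding
  control on real data.

One seed drives everything; per-stage substreams are spawned
deterministically from it, so output is bit-identical for identical
(config, seed) and insensitive to stage order.

## Numerical choices and degenerate inputs

* Quintile/percentile ties: average-rank, block-to-one-side (above).
* Banding edges half-open at 2 and 4 (above); weighted score clipped at
  [0, 5] against float round-off.
* Logistic/Cox separation and rare-carrier handling: pinned coefficients,
  explicit errors for genuine separation of the exposure of interest.
* Breslow baseline tail extension beyond follow-up (above).
* Bootstrap: B ≥ 100 enforced; > 5% failed resamples aborts.
* Bonferroni and nominal flags use strict `<`.
* Exclusion cascade removes the union of criterion sets; the ledger's
  inclusion–exclusion identity (`final n = initial n − |union|`) is asserted
  on every call.
* n = 0 cohorts are valid (empty table, full schema); zero-event Cox fits,
  constant standardization inputs, empty rank vectors, and out-of-range
  probabilities all raise informative errors.

## Problem sizes

Tests and the acceptance script use cohorts of 50,000 (parameter recovery,
mediation, grids), 500 replicates of 5,000 for the type-I-error calibration
of the product-term test, 200 rounds × B = 300 for bootstrap coverage, and
replicate means over 50–100 cohorts of 50,000 for the AP split. These sizes
resolve every assertion at ≥ 3σ while keeping a full run in the minutes
range on one CPU.

## Known limitations

* OR approximates RR in the decomposition; at ≈ 22% prevalence the
  approximation overstates RRs, which is why decomposition results are
  reported with the contrast definition and the caveat attached.
* The generator's lifestyle factors are mutually independent and
  time-fixed; no reverse causation, no measurement error, no EHR coding
  noise — passing tests demonstrate estimator behavior under the assumed
  structure, not robustness to those real-data features.
* The BMI-threshold incidence sub-analysis needs follow-up BMI columns that
  the default generator does not produce; its eligibility definition is
  explicit and configurable because published denominators for such
  sub-analyses are often ambiguous.
* Risk-by-75 extrapolates beyond observed follow-up (above).
* No competing-risk or frailty machinery; no time-varying covariates.
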