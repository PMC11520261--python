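# Methods

This note documents the statistical models, the synthetic data-generating
process, the numerical choices, and the limitations of `drclaims`.

## Estimand and sign conventions

The target is the 5-year average treatment effect on incident heart
failure for a two-arm new-user comparison: with `S_a(t)` the marginal
probability of remaining HF-free at horizon `t` had everyone started drug
class `a`,

    ATE(t) = rate_1(t) − rate_0(t) = (1 − S_1(t)) − (1 − S_0(t)),

where arm 1 is the treated class (insulin in the motivating comparison)
and arm 0 the comparator.  **Positive ATE means the treated class has the
higher HF rate.**  The personalized score is on the survival scale,
`S(x) = Ŝ_1(t|x) − Ŝ_0(t|x)`, so **positive scores favor the treated
class**; under correctly specified models the conditional rate difference
is `−S(x)` — the score-favorable region is where the treated drug is *not*
worse.  The synthetic generator's `GroundTruth` carries both scales
(`ate_t` on survival, `hf_rate_diff = −ate_t` on rates).

## Cohort construction

Arm assignment follows an intention-to-treat, sustained-use rule: a class
is sustained when its first fill is followed by a second fill of the same
class within `[183, 365]` days; among sustained classes the earliest
first fill wins, same-day ties broken by a fixed priority order.
Inclusion requires ≥1 HbA1c result, ≥365 cumulative days of qualifying
coverage (contiguity not required), no HF phecode (428.1–428.4) strictly
before the index date, and not likely type-1 diabetes.  The likely-T1DM
proxy — more T1DM than T2DM diagnosis codes, or T1DM codes with zero T2DM
codes — is a transparent, testable rule; claims studies rarely publish
their exact criterion, and this one is a configuration point.  Exclusion
reasons are attributed in a fixed first-failing order
(no-arm → no-HbA1c → coverage → T1DM → prior-HF) so attrition tables are
deterministic and sum exactly.

Follow-up runs from the index date to the first post-index HF phecode or
the last follow-up date (latest coverage end), whichever is earlier;
same-day events are recorded as half a day so all times are positive.
Baseline covariates use the half-open lookback window `[index−365,
index)`: the most recent value per lab (the clinically standard baseline
summary), per-phecode diagnosis counts, auxiliary-medication fill counts,
and disease duration in months from the first T2DM code.  Index-day
claims count as post-index, so no covariate touches on-or-after-index
information.

## Design matrix

Phecode count features with prevalence strictly below 5% are dropped.
Missing labs are mean-imputed on the analysis cohort.  The comorbidity
counts are summarized by their first three principal components computed
on standardized counts (correlation PCA — count scales differ by orders
of magnitude), with a deterministic sign convention (largest-magnitude
loading positive).  By default the counts enter the models only through
the PCs; a switch includes the filtered raw counts as well.

Age enters through a 3-column B-spline basis with 3 equally spaced knots
spanning the 5th–95th age percentiles, clamped at the boundaries.  Three
knots with a degree-1 (piecewise-linear) B-spline give exactly three
basis functions `B_1..B_3` with `ΣB_k(age) = 1`; this matches the "three
age basis variables, three sets of coefficient estimates" structure in
which every covariate effect is allowed to vary smoothly with age.
Higher-degree bases are available via a keyword (at the cost of more
columns).  The full design is `[B_1..B_3] ∪ {B_k · X_j}` — `3(1+p)`
columns.  Continuous covariates are standardized (statistics stored for
prediction reuse); binary covariates are left on their natural scale so
balance diagnostics stay interpretable; constant covariates are dropped
with a warning.

## Nuisance models

Both the logistic propensity model and the two arm-specific Cox outcome
models use a two-stage adaptive LASSO:

1. an initial ridge fit — logistic: L2 with `C = 1.0` on the standardized
   design; Cox: Newton with L2 strength 0.01 per observation — gives
   preliminary coefficients `β̃`;
2. a weighted-L1 fit with penalty weights `w_j = 1/(|β̃_j| + 1e−6)`
   (γ = 1).  The intercept and the three age-basis columns (forced
   confounders) are never penalized.

The Cox L1 path is solved by the glmnet-style coordinate descent in
scikit-survival's Coxnet (per-column penalty factors, Breslow ties); the
logistic path by an in-package FISTA proximal-gradient solver, because no
installed logistic implementation supports per-column penalty weights and
exemptions.  Convergence tolerance is 1e−7 on relative coefficient
change, max 500 iterations.

The penalty is tuned by 10-fold cross-validation with folds keyed to a
seeded permutation of sorted patient ids (so refitting with permuted rows
reproduces the fit exactly).  CV deviance is the held-out binomial
deviance (logistic) or the Verweij–Van Houwelingen partial-likelihood
deviance (Cox).  The default selection rule is **1-SE** (the sparsest
model within one fold-level standard error of the minimum) rather than
the plain minimum: on pure-noise designs the CV curve shows deviance dips
of the order of the CV noise — driven by dataset-level spurious
correlations that no resampling within the dataset can detect — and the
minimum rule then systematically admits noise columns.  Measured on
n = 5000, p = 50 pure-noise designs, the 1-SE rule keeps the per-column
false-inclusion rate at ≈ 7% while retaining strong true signals in
every replicate; `lambda_rule="min"` remains available.

Conditional survival is predicted as
`Ŝ(t|x) = exp(−Λ̂_0(t)·exp(xβ̂))` with the Breslow cumulative baseline
hazard `Λ̂_0` (equal to the Nelson–Aalen estimator when no covariates are
selected).  Horizons beyond the last observed event time carry the last
hazard step forward and are flagged.

## Doubly robust estimation

For each arm `a` the per-patient pseudo-value is

    ψᵢᵃ = Ŝ_a(t|Xᵢ) + 1{Aᵢ=a}/π̂_a(Xᵢ) · Δᵢ(t)/Ĝ_a(min(Tᵢ,t)⁻)
          · (1{Tᵢ>t} − Ŝ_a(t|Xᵢ)),

where `Δᵢ(t) = 1{Tᵢ>t} + 1{Tᵢ≤t}·eventᵢ` indicates a known t-year status
and `Ĝ_a` is the arm-specific Kaplan–Meier estimator of the censoring
distribution, evaluated with left limits (outcome events are taken to
precede censorings at tied times).  Censoring is assumed independent
within arm; the generator offers a covariate-dependent censoring mode
precisely to stress that assumption.  `Ŝ_a(t) = mean(ψᵃ)` over the
trimmed cohort and `ATE = mean(ψ⁰ − ψ¹)`.  Patients with estimated
propensity outside `(0.01, 0.99)` (configurable) are trimmed first.  The
SE is the empirical standard deviation of the per-patient contrast
contributions divided by √n — valid to first order when both nuisance
models are correct, and verified by coverage simulation; a seeded
patient-level bootstrap (predictions held fixed) is available as a
cross-check.  At `t = 0` the estimator returns exactly 0.

## Score-specific effects

The score-specific ATE curve is a Nadaraya–Watson local-constant
smoother of the per-patient doubly robust contrasts `ψ⁰ᵢ − ψ¹ᵢ` against
the score, with a Gaussian kernel and Silverman's rule-of-thumb
bandwidth on the score, evaluated on ≥50 equally spaced grid points over
the 1st–99th score percentiles.  Pointwise variances use the
kernel-weighted residual sandwich, floored by the global residual
variance propagated through the same kernel weights — in sparse score
tails the purely local variance is estimated from a handful of points and
can collapse to near zero.  Because the curve's pointwise bands are just
that — pointwise — roughly 5% of grid points are expected to sit outside
±2 SE even under a flat truth; flatness checks therefore assert ≥90% of
grid points within 2 SE plus a 4-SE cap everywhere, not a joint 2-SE
band.  Subgroup ATEs re-run the AIPW estimator within `S > 0` / `S ≤ 0`
(full-cohort nuisance fits; the pipeline falls back to a median split
when all scores share one sign, and records this in the manifest).  No
sample-splitting is used by default; contributions are recycled from the
overall AIPW fit, which keeps the cost at O(n·grid).

## Synthetic data-generating process

The generator emulates the structure of a large T2DM claims cohort.
Defaults are anchored to the published cohort description of the
motivating study population: age ~ Normal(66.24, 9.86²), 48.06% male,
HbA1c 8.52 (1.1) %, cholesterol 170.87 (22.35), HDL 45.51 (6.35), LDL
90.04 (17.51) mg/dL, with 10% MCAR lab missingness (HbA1c fully
observed); 50 zero-inflated-Poisson phecode features with prevalences
uniform on [0.01, 0.40] (`count = Bernoulli(prev) · (1 + Poisson(1.5))`).
The truth design vector is
`[1, z_age, z_age²−1, male, z_labs..., z_age·z_HbA1c]` with continuous
covariates standardized by the configured moments.  Treatment is
Bernoulli(expit(z·θ)) with default θ giving ≈75% treated and strong
age/HbA1c confounding with an age-varying (interaction) component.
Event times are arm-specific Weibull proportional hazards (shape 1.2,
scales 14 / 23 years) — chosen, unlike the semiparametric Cox fits used
for analysis, because the Weibull closed form yields exact oracles; the
default parameters produce true 5-year HF rates of ≈0.28 (treated) vs
≈0.17 (comparator), a rate difference of ≈0.11, in the vicinity of the
published comparison.  Censoring is `min(Exponential(0.25/yr),
administrative end 5.4y)`, giving a median follow-up of ≈2.4 years; an
optional age-dependent censoring rate supports stress tests.

The raw-claims mode scripts each patient: most are "clean" (sustained
fills, labs, full coverage), while configured fractions violate exactly
one curation rule (single fill; refill at 1–5 months; missing HbA1c;
201-day coverage; T1DM-dominant codes; pre-index HF) or carry two
sustained classes (earliest wins, 20% of them same-day ties).  The
generator records the arm, index date and first-failing exclusion reason
each patient *should* receive, enabling exact round-trip tests — the
acceptance suite requires 100% agreement on 1,000 patients.

`true_survival` returns the marginal arm-specific survival either in
closed form (no covariate effects) or by Monte Carlo over ≥10⁶ covariate
draws with its standard error; `ground_truth` adds the conditional-effect
oracle `cate_fn`.

What the generator does **not** emulate: informative censoring by
default, treatment switching and adherence, code-vocabulary noise
(synthetic ICD-style codes map 2-to-1 onto phecodes), calendar-time
trends, and correlated comorbidity structure (phecode features are
independent given their prevalences).  Passing tests therefore validate
the estimation machinery under the stated assumptions, not robustness to
these real-data complications.

## Simulation-study sizes and scenarios

The replication harness uses four scenarios — both nuisances correct, one
broken (each direction), both broken — where "correct" is an unpenalized
fit on the generator's own design columns and "broken" is an
intercept-only model that ignores all confounders.  The scenario
generator (labs fully observed, phecode block off) uses strong age/HbA1c
confounding so that the doubly misspecified analysis is biased by ≈+0.05
while each singly-correct analysis stays within ±0.01 of the truth.
Default study sizes: 200 replicates at n = 5,000 for bias/coverage,
n = 20,000 single runs for oracle recovery and heterogeneity, n = 10,000
for balance — sizes at which the Monte Carlo error of each summary is
comfortably below the property being asserted.  The adaptive-LASSO
pipeline is validated separately at the selection level (50 replicates
per setting) because its CV loops dominate runtime.

## Known limitations

* The influence-function SE ignores nuisance-estimation variability; it
  is validated by coverage simulation under correct specification, not
  under misspecification.
* Mean imputation of labs is the design's stated remedy and is only
  defensible under (approximately) MCAR missingness — which the generator
  produces by construction.
* With heavy shrinkage on small cohorts both Cox fits can collapse to
  their baselines, making the score degenerate; the pipeline then reports
  the overall ATE as a constant "curve" rather than failing.
* Competing risks (death before HF) and multi-arm (multinomial
  propensity) comparisons are out of scope; one comparator per run.
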