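# drclaims

Doubly robust comparative-effectiveness analysis of insurance-claims
cohorts, built around the question the package was written for: do
patients with type 2 diabetes who start **insulin** face a higher 5-year
risk of incident **heart failure (HF)** than patients starting an
alternative glucose-lowering class (GLP-1 receptor agonists, DPP-4
inhibitors, SGLT2 inhibitors)?

Real claims data for such a study are proprietary, so the package ships a
seeded synthetic claims generator with closed-form/Monte-Carlo ground
truth; every stage of the pipeline is exercised and validated end to end
against that truth.

## What it does

1. **Cohort construction** from dated claim tables (pharmacy fills,
   diagnoses, labs, coverage spans): new-user arm assignment by the
   earliest *sustained* drug class (a second fill of the same class 6–12
   months after the first), inclusion/exclusion (HbA1c on record, ≥1 year
   of qualifying coverage, no prior HF, not likely type-1 diabetes), HF
   outcome from phecodes 428.1–428.4, and 1-year-lookback baseline
   covariates (most recent labs, phecode comorbidity counts, auxiliary
   medication counts).
2. **Design matrix**: rare-feature filtering (<5% prevalence), mean
   imputation of labs, the first 3 comorbidity principal components, and
   an age-varying coefficient expansion — every covariate `X_j` enters as
   interactions `B_k(age)·X_j` with a 3-column age B-spline basis
   `B_1..B_3` (partition of unity), so each fitted effect is a smooth
   function of age.
3. **Nuisance models** by two-stage **adaptive LASSO** (ridge initial fit,
   then weighted L1 with penalty `w_j = 1/(|β̃_j|+ε)`, 10-fold seeded CV):
   a logistic propensity model `π(X) = P(insulin | X)` and two arm-specific
   Cox proportional-hazards outcome models with Breslow baseline hazards.
4. **Estimation**: IPW weights with propensity trimming, covariate-balance
   diagnostics (standardized mean differences before/after weighting),
   weighted Kaplan–Meier curves, and the **AIPW** (augmented IPW) 5-year
   HF-rate difference

   `ψᵢᵃ = Ŝₐ(t|Xᵢ) + [1{Aᵢ=a}/π̂ₐ(Xᵢ)] · [Δᵢ(t)/Ĝₐ(min(Tᵢ,t)⁻)] · (1{Tᵢ>t} − Ŝₐ(t|Xᵢ))`

   with arm-specific Kaplan–Meier censoring correction `Ĝₐ`;
   `ATE = (1−mean ψ¹) − (1−mean ψ⁰)`, positive = insulin has the higher HF
   rate; SEs from the influence-function variance (bootstrap cross-check).
   The estimator is consistent if *either* nuisance model is correct.
5. **Heterogeneity**: the personalized score
   `S = Ŝ_insulin(t|X) − Ŝ_comparator(t|X)` (positive favors insulin), a
   Nadaraya–Watson smoothed score-specific ATE curve with pointwise CIs,
   and AIPW re-estimation within `S`-defined subgroups.

## Worked example

```python
from drclaims.pipeline import RunConfig, run_comparison

cfg = RunConfig(mode="synthetic", output_dir="out", seed=7,
                sim={"n_patients": 4000})
bundle = run_comparison(cfg)
a = bundle["ate"]
print(f"5-year HF rate, insulin:    {a.rate_treated:.3f}")
print(f"5-year HF rate, comparator: {a.rate_control:.3f}")
print(f"ATE (rate difference):      {a.ate:.3f}  SE {a.se:.3f}")
print(f"95% CI: ({a.ci[0]:.3f}, {a.ci[1]:.3f})   n={a.n_used}")
```

prints (exactly, for this seed):

```
5-year HF rate, insulin:    0.278
5-year HF rate, comparator: 0.161
ATE (rate difference):      0.117  SE 0.024
95% CI: (0.069, 0.165)   n=3139
```

i.e. on this synthetic cohort the insulin arm's adjusted 5-year HF rate is
27.8% versus 16.1% under the comparator — an 11.7-point excess with CI
well away from 0 (the generator's true difference is ≈ 0.11).  The output
directory also receives the attrition table, balance table (SMDs before
IPW reach ≈ 0.36 and fall below 0.1 after), weighted KM curves, the CATE
curve with its score histogram, subgroup estimates, serialized fits and a
reproducibility manifest.

The same analysis runs from the shell:

```bash
drclaims simulate --out tables/ --seed 7 --n-patients 4000
drclaims run-all --config run.yaml
drclaims sim-study --replicates 200 --n-patients 5000
```

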