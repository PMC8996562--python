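# prefiv

Treatment-effect estimation from clustered observational registries,
built around the comparison of four statistical strategies on
multicenter acute-stroke data: individual-level logistic regression,
GEE with exchangeable within-hospital correlation, hospital-level
ecological regression, and instrumental-variable analysis using the
hospital's treatment *preference* as the instrument — together with a
calibrated synthetic-registry generator in which the true treatment
effect is known by construction.

## The problem

In observational comparative-effectiveness studies, treatment
assignment depends on prognostic factors (measured and unmeasured), so
naive regression estimates mix the treatment effect with *confounding
by indication*: sicker patients are selected into (or out of)
treatment for reasons that also drive their outcomes. In multicenter
registries, however, hospitals differ widely in how often they use a
treatment for reasons of local practice style rather than patient mix.
That variation can be exploited: the proportion of a hospital's
patients who receive the treatment,

    pi_h = (treated patients in hospital h) / n_h,

is a *preference-based instrument* — associated with each patient's
treatment, but (if the instrument assumptions hold) related to outcome
only through treatment and unrelated to patient-level confounders.

The package implements, for a binary treatment T and binary outcome Y
(good functional status, modified Rankin Scale 0–2) with case-mix
covariates X:

* **Logistic regression** (IRLS maximum likelihood):
  `logit P(Y=1) = b0 + b_T T + b'X`, reporting OR = exp(b_T).
* **GEE** with logit link and exchangeable (compound-symmetry) working
  correlation over hospitals, moment estimator of the within-hospital
  correlation rho, cluster-robust sandwich errors.
* **Ecological regression**: volume-weighted least squares of the
  hospital's % good outcome on its % treated (plus hospital-level
  case-mix means); the slope is percentage points of outcome per 1%
  utilization.
* **Two-stage IV (predictor substitution)**: stage 1 logistic of T on
  pi_h (+ case-mix + volume); stage 2 logistic of Y on the stage-1
  predicted probability (+ case-mix); hospital-cluster bootstrap CI.
* **Linear two-stage least squares** on the probability scale, giving
  a risk difference, with hospital-cluster sandwich errors.

IV validity diagnostics: first-stage partial R², the F-statistic
`[R² (n − 1 − K)] / [(1 − R²) K]` with the F > 10 rule of thumb, a
Durbin–Wu–Hausman endogeneity test in control-function form, and
volume-weighted hospital-level associations between the instrument and
each case-mix variable.

The synthetic generator (`Scenario`, `generate_registry`) emulates a
17-hospital thrombectomy registry — volumes 23–405, IVT-like (66–87%)
or GA-like (0–93%) utilization spread, outcome prevalence ≈ 38%,
realistic case-mix marginals — with an optional unmeasured severity
variable U entering both the treatment and the outcome model, and
deliberate instrument-invalidation knobs for negative controls. A
counterfactual oracle (`describe_truth`) returns the scenario's true
marginal odds ratio and risk difference.

## Worked example

```python
import prefiv as pv

scenario = pv.make_ivt_like_scenario()          # 17 hospitals, IVT-like practice variation
table, truth = pv.generate_registry(scenario)   # deterministic given scenario.seed
comparison = pv.run_comparison(table, bootstrap_reps=200, seed=1)
print(comparison.to_frame()[["method", "adjusted", "scale", "estimate", "ci_low", "ci_high"]])
```

prints (2,612 patients; the scenario's true marginal OR is 1.241, true
marginal risk difference 0.050):

```
      method  adjusted                     scale  estimate  ci_low  ci_high
    logistic     False                odds_ratio     1.855   1.517    2.268
    logistic      True                odds_ratio     1.668   1.340    2.076
         gee     False                odds_ratio     1.848   1.656    2.062
         gee      True                odds_ratio     1.664   1.480    1.871
  ecological     False percentage_point_per_1pct     0.065  -0.188    0.317
  ecological      True percentage_point_per_1pct     0.065  -0.207    0.337
iv_two_stage     False                odds_ratio     1.369   0.476    2.793
iv_two_stage      True                odds_ratio     1.169   0.329    2.116
   iv_linear     False           risk_difference     0.065  -0.122    0.252
   iv_linear      True           risk_difference     0.060  -0.113    0.232
```

The pattern is the one this kind of comparison is designed to expose:
the scenario has unmeasured severity pushing sicker patients *away*
from treatment, so the individual-level odds ratios (1.67–1.85) are
biased well above the true marginal OR of 1.24, and case-mix
adjustment removes only part of the gap; the IV estimates sit near the
truth (two-stage OR 1.17; linear RD 0.060 vs true 0.050) at the price
of much wider intervals. Diagnostics for the same registry:
first-stage partial R² = 0.0261, F = 70.1 (strong instrument), DWH
p = 0.75 (no detectable endogeneity left), GEE rho = −0.0023
(negligible within-hospital correlation, so GEE ≈ logistic).

The same analyses are available from the shell:

```bash
prefiv generate --preset ivt_like --seed 4 --out registry.csv   # + registry.csv.truth.json
prefiv compare registry.csv --bootstrap-reps 500 --out comparison
prefiv diagnose registry.csv
prefiv simulate --config study.yaml --seed 1 --out study
```

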