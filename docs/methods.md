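# Methods

## Estimands and why four estimators

For a binary treatment T and binary outcome Y in a multicenter
registry, the package distinguishes three estimands:

* the **conditional odds ratio** exp(beta_T) from a patient-level
  logistic model given case-mix X (what logistic regression and GEE
  target when adjusted);
* the **marginal odds ratio**, odds(E[Y(1)])/odds(E[Y(0)]), over the
  registry's patient population;
* the **marginal risk difference** E[Y(1) − Y(0)] (what the linear IV
  and, on its percentage scale, the ecological slope target).

Because the odds ratio is noncollapsible, the marginal OR differs from
the conditional OR even without confounding, so cross-method bias is
only well defined on the risk-difference scale. All simulation
summaries therefore convert every method to a risk-difference analogue
— logistic/GEE and the two-stage IV via the average marginal effect of
the fitted model (mean fitted probability with the treatment term at 1
minus at 0), the ecological slope and linear IV directly — and compare
those to the generator's true marginal risk difference. Native-scale
estimates are reported alongside but never cross-compared.

In simulation coverage summaries each method's CI is held against its
own natural estimand: the conditional OR for adjusted logistic/GEE,
the marginal OR for their unadjusted versions and the two-stage IV,
the marginal risk difference for the linear IV and ecological slope.

## Numerical core

* **Logistic (IRLS / Newton scoring).** Convergence when max |score| <
  1e−8 or max coefficient change < 1e−10; step-halving guarantees a
  nondecreasing log-likelihood. Divergence is declared when any
  coefficient exceeds 30 on the standardised scale (coefficient times
  column SD; raw scale for constant columns), or immediately for a
  constant response; both raise a separation error rather than
  returning garbage. Rank deficiency is detected by pivoted QR and the
  error names a collinear column.
* **WLS.** Closed-form via QR least squares on the sqrt-weighted
  design; model covariance uses the weighted residual variance with
  n − p degrees of freedom.
* **Cluster-robust sandwich.** Score contributions w_i x_i (y_i − μ_i)
  summed within clusters; bread is the unscaled inverse information;
  the small-sample factor G/(G−1) is applied (G clusters). With every
  observation its own cluster this is the HC0 sandwich times n/(n−1).
* **GEE (exchangeable).** Alternates a GLS coefficient update using
  the closed-form inverse of the compound-symmetry correlation matrix
  with a moment update of rho from standardised Pearson residuals
  (all within-cluster pairs, denominator N_pairs − p, scaled by the
  moment estimate of the dispersion phi). rho is clamped to the
  exchangeable-validity interval (−1/(max cluster size − 1), 1).
  Reported intervals use the cluster-robust sandwich, again with the
  G/(G−1) factor (statsmodels omits it; the cross-check tests account
  for exactly this factor). Non-convergence after 200 iterations
  returns the partial fit flagged `converged=False`. With singleton
  clusters there are no residual pairs; rho is reported as 0 and the
  update reduces exactly to IRLS.

## Instrument, IV estimators, diagnostics

The instrument is the hospital's realized utilization pi_h (constant
within hospital). A leave-one-out variant, (treated in h − own
treatment)/(n_h − 1), is offered because the plain version mechanically
contains the patient's own treatment; the plain version is the default
for fidelity to how preference instruments are usually defined.

* **Two-stage predictor substitution.** Stage 1: logistic of T on pi_h
  (+ case-mix and hospital volume per 100 patients when adjusted).
  Stage 2: logistic of Y on the stage-1 predicted probability
  (+ case-mix). The coefficient is the log-OR for moving the predicted
  treatment probability from 0 to 1. This estimator is reported
  exactly as described — predictor substitution is known to be
  inconsistent for conditional ORs under noncollapsibility, which is
  documented here rather than "fixed". Default CI: hospital cluster
  bootstrap (hospitals resampled with replacement, 500 replicates,
  seeded; resampled copies get fresh cluster labels; the percentile
  interval is widened to bracket the point estimate if needed).
  Analytic alternative: cluster sandwich on stage 2, which ignores
  stage-1 uncertainty — used by default inside large simulation loops.
* **Linear 2SLS.** Stage-1 linear projection of T on instrument +
  exogenous covariates; stage-2 regression of Y on fitted T +
  covariates; residuals for the sandwich are formed with the observed
  T (the proper 2SLS residual), clusters = hospitals.
* **Strength.** Partial R² is the raw increment in first-stage linear
  R² from adding the instrument to the covariate-only model (with no
  covariates it is the plain R²); F = [R²(n−1−K)]/[(1−R²)K] with
  K = 1. The formula presumes a linear first stage, which is why the
  first stage of the diagnostics is always linear even though the
  two-stage estimator's first stage is logistic.
* **Endogeneity (Durbin–Wu–Hausman).** Control-function form: the
  linear first-stage residual is added to a linear outcome model
  Y ~ T + X + r̂, and its Wald statistic — with HC1
  heteroskedasticity-robust variance — is referred to χ²(1).
  HC1 rather than the 17-cluster sandwich keeps the test close to its
  nominal level (few-cluster sandwich variances are anti-conservative
  in this design); the calibration suite verifies a 3–8% rejection
  rate at nominal 5% under exogeneity.
* **Instrument–confounder association.** For each case-mix variable, a
  volume-weighted hospital-level regression of the covariate's
  hospital mean on pi_h; raw p-values (t, H−2 df), no multiplicity
  correction, and a flag that fires if any p < 0.05. This mirrors the
  qualitative "associated with some confounders" screen; note that
  because pi_h is the *realized* utilization, finite hospital samples
  induce small mechanical associations with case-mix variables that
  strongly influence treatment, so the flag is a screen, not a test
  with controlled family-wise error.

## Synthetic-registry generator

Per hospital h: volume n_h log-uniform on [23, 405]; preference logits
equally spaced between logit(p_lo) and logit(p_hi) and randomly paired
with hospitals; hospital outcome intercept b_h ~ N(0, sd²) (default
sd = 0, so the exclusion restriction holds by construction). Because
patient-level terms smooth the expected utilization toward 1/2, the
preference logits are inflated by sqrt(1 + 0.346·Var(noise)) — the
standard logistic-normal approximation — so the *expected* utilization
still spans the preference range; the spacing on the logit scale is
unchanged. Per patient: case-mix from independent marginals (age and
NIHSS truncated normal, NIHSS rounded and floored at 2 per the
inclusion criterion; onset-to-ED lognormal; sex and comorbidities
Bernoulli — correlations between covariates are deliberately not
modelled, since only marginals are calibrated), unmeasured severity
U ~ N(0,1), then

    T ~ Bern(expit(alpha_h + gamma'Xc + delta·U))
    Y ~ Bern(expit(beta0 + b_h + beta_T·T + theta'Xc + phi·U))

with Xc mean-centred covariates. beta0 is auto-calibrated by the same
logistic-normal approximation so the marginal outcome prevalence is
≈ 0.38. Everything is deterministic given the scenario seed.

Presets: `ivt_like` (preference 66–87%, delta = −0.5, phi = −0.5:
sicker patients less likely treated and less likely to recover, so the
crude OR is biased upward, conditional effect OR 1.3) and `ga_like`
(preference 0.5–93%, delta = +0.5: sicker patients *more* likely
treated, conditional OR 0.8). The GA preference floor is 0.005 rather
than exactly 0 (the logit is unbounded); low-preference hospitals
still realize 0% treated regularly. Case-mix coefficients were chosen
once to reproduce the qualitative treated-vs-untreated imbalances of a
thrombectomy cohort (strong atrial-fibrillation and previous-stroke
contraindication effects for IVT) with a total patient-level logit SD
under 1.

Deliberate invalidation knobs for negative controls:
`hospital_outcome_sd` (random direct hospital effects),
`hospital_outcome_pref_effect` (outcome level correlated with
preference — an exclusion-restriction violation) and
`hospital_age_pref_effect` (hospital mean age shifted with preference —
an instrument–confounder association that the diagnostics flag).

**Ground truth.** `describe_truth` draws a Monte Carlo population,
computes both potential-outcome *probabilities* per subject (no
Bernoulli noise, so a null effect gives a risk difference of exactly
zero) and averages them into the marginal risk difference and marginal
OR. `calibrate_beta_for_rd` inverts this oracle by bisection with
common random numbers to hit a requested true risk difference.

**What the generator does not emulate:** correlated case-mix,
inter-hospital transfers, time trends, missing outcomes, ordinal
functional scores, and treatment-effect heterogeneity beyond what the
logit link induces. Passing tests therefore demonstrate estimator
behaviour under the assumed data-generating process, not fidelity to
any particular registry's joint distribution.

## Study conditions used by the test and acceptance suites

Chosen once as realistic desk-scale conditions:

* **Recovery benchmark:** 17 hospitals of 4,500–8,000 patients
  (≈ 100,000 total), preference 5–95%, delta = 0.9, phi = −0.9
  (naive risk-difference bias ≈ −0.08), beta_T calibrated so the true
  marginal risk difference is 0.05.
* **DWH calibration:** 17 hospitals of 60–180 patients (≈ 2,000
  total), IVT-like measured case-mix effects, delta = phi = 0, 1,000
  replicates in the test suite (200 in the acceptance script).
* **Negative control:** IVT-like confounding at 600–1,800 patients per
  hospital, with `hospital_outcome_pref_effect = 0.8` and
  `hospital_age_pref_effect = 5` years per preference-logit unit,
  paired by seed with the valid-instrument version.
* Coverage and null-calibration simulations run at 150 replicates of
  ≈ 10,000-patient registries and 40 replicates of ≈ 5,000-patient
  registries respectively — sizes at which binomial Monte Carlo bands
  are tight enough to be informative while the whole suite stays quick.

## Known limitations and open choices

* The printed instrument-strength F values that motivated the formula
  (41.2 at partial R² = 1.6%, n = 3,267) are not reproducible from the
  formula itself, which gives 53.1 for those inputs; the package
  computes the formula as stated and the test suite asserts the
  discrepancy instead of matching the printed value.
* Whether a preference-IV analysis of this design should report the
  two-stage logistic OR or the linear-GMM risk difference is
  ambiguous in practice; both estimators are provided and reported
  side by side.
* The two-stage bootstrap treats hospitals as the only resampling
  unit; with 17 clusters the percentile interval is itself noisy.
* The ecological model fits up to 10 parameters on 17 hospital
  observations when adjusted and warns accordingly.
* Hospital-level confounder-association tests use realized utilization
  and are mechanically correlated with case-mix in small hospitals
  (see above); leave-one-out instruments mitigate but do not remove
  this.
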