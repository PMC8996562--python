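"""Synthetic multicenter registry generator.

Emulates the statistical structure of a nationwide acute-stroke
registry: 17 hospitals with widely varying volumes, strong
between-hospital variation in treatment utilization (hospital "practice
style"), patient-level case-mix that influences both treatment
assignment and outcome (confounding by indication), and an optional
unmeasured severity variable U entering both models on the logit scale.
The true conditional treatment effect is known by construction, and a
counterfactual Monte Carlo oracle reports the implied marginal risk
difference and marginal odds ratio.

Generative model, per hospital h and patient i:

    T_i ~ Bernoulli( expit( alpha_h + gamma' Xc_i + delta * U_i ) )
    Y_i ~ Bernoulli( expit( beta0 + b_h + beta_treat * T_i
                            + theta' Xc_i + phi * U_i ) )

with Xc the mean-centred case-mix covariates and U ~ N(0, 1).  Hospital
preference intercepts alpha_h are equally spaced on the logit scale
across ``preference_range`` (scaled so the *expected* utilization matches
the target despite patient-level noise), so the hospital-preference
instrument is valid by construction: alpha_h enters only the treatment
model.  Setting ``hospital_outcome_sd`` or the deliberate-violation
knobs below breaks that validity for negative-control experiments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .registry import CASE_MIX, COLUMNS, PatientTable


@dataclass
class CovariateMarginals:
    """Marginal distributions of the case-mix covariates.

    Age and NIHSS are (rounded) truncated normals, onset-to-ED time is
    lognormal parameterised by its median, comorbidities and sex are
    independent Bernoulli.  Defaults reproduce a thrombectomy cohort:
    median age ~72 y, median NIHSS ~16, median onset-to-ED ~135 min,
    52% male, and comorbidity prevalences of 17/24/52/30% for previous
    stroke, atrial fibrillation, hypertension and hypercholesterolemia.
    """

    age_mean: float = 72.5
    age_sd: float = 14.8
    age_min: float = 18.0
    age_max: float = 110.0
    nihss_mean: float = 16.0
    nihss_sd: float = 6.0
    nihss_min: float = 2.0  # inclusion criterion: deficit of at least 2 points
    nihss_max: float = 42.0
    onset_median: float = 135.0
    onset_log_sd: float = 0.78
    p_male: float = 0.52
    p_prev_stroke: float = 0.17
    p_atrial_fib: float = 0.24
    p_hypertension: float = 0.52
    p_hypercholesterolemia: float = 0.30

    def moments(self) -> dict[str, tuple[float, float]]:
        """Analytic (mean, variance) of every covariate, used for
        centring and for logit-scale variance bookkeeping."""
        a = (self.age_min - self.age_mean) / self.age_sd
        b = (self.age_max - self.age_mean) / self.age_sd
        age = stats.truncnorm(a, b, loc=self.age_mean, scale=self.age_sd)
        a = (self.nihss_min - self.nihss_mean) / self.nihss_sd
        b = (self.nihss_max - self.nihss_mean) / self.nihss_sd
        nihss = stats.truncnorm(a, b, loc=self.nihss_mean, scale=self.nihss_sd)
        s2 = self.onset_log_sd**2
        onset_mean = self.onset_median * np.exp(s2 / 2)
        onset_var = (np.exp(s2) - 1) * onset_mean**2
        out = {
            "age": (float(age.mean()), float(age.var())),
            "male": (self.p_male, self.p_male * (1 - self.p_male)),
            "nihss": (float(nihss.mean()), float(nihss.var())),
            "onset_to_ed_min": (float(onset_mean), float(onset_var)),
        }
        for name, p in [
            ("prev_stroke", self.p_prev_stroke),
            ("atrial_fib", self.p_atrial_fib),
            ("hypertension", self.p_hypertension),
            ("hypercholesterolemia", self.p_hypercholesterolemia),
        ]:
            out[name] = (p, p * (1 - p))
        return out


def _zero_coefs() -> dict[str, float]:
    return {name: 0.0 for name in CASE_MIX}


@dataclass
class Scenario:
    """Full generative specification of one synthetic registry.

    ``delta`` and ``phi`` are the log-odds effects of the unmeasured
    severity variable U on treatment and outcome; ``delta = phi = 0``
    means no unmeasured confounding.  ``hospital_outcome_sd`` adds
    random hospital outcome intercepts, and the two ``*_pref_effect``
    knobs correlate hospital outcome level (exclusion-restriction
    violation) or hospital mean age (instrument-confounder association)
    with the centred preference logit — deliberate instrument
    invalidators for negative-control studies.
    ``baseline_outcome_logit=None`` auto-calibrates the intercept so the
    marginal outcome prevalence is near ``target_outcome_prevalence``.
    """

    n_hospitals: int = 17
    volume_range: tuple[int, int] = (23, 405)
    preference_range: tuple[float, float] = (0.2, 0.8)
    beta_treat: float = 0.0
    gamma: dict[str, float] = field(default_factory=_zero_coefs)
    theta: dict[str, float] = field(default_factory=_zero_coefs)
    delta: float = 0.0
    phi: float = 0.0
    hospital_outcome_sd: float = 0.0
    hospital_outcome_pref_effect: float = 0.0
    hospital_age_pref_effect: float = 0.0
    baseline_outcome_logit: float | None = None
    target_outcome_prevalence: float = 0.38
    covariate_marginals: CovariateMarginals = field(default_factory=CovariateMarginals)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.preference_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("preference_range must lie within [0, 1]")
        if self.volume_range[0] < 1:
            raise ValueError("volume_range minimum must be >= 1")
        if self.hospital_outcome_sd < 0:
            raise ValueError("hospital_outcome_sd must be >= 0")
        self.gamma = {**_zero_coefs(), **self.gamma}
        self.theta = {**_zero_coefs(), **self.theta}

    def replace(self, **kw) -> "Scenario":
        return dataclasses.replace(self, **kw)

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["volume_range"] = list(self.volume_range)
        d["preference_range"] = list(self.preference_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        d = dict(d)
        if "covariate_marginals" in d and isinstance(d["covariate_marginals"], dict):
            d["covariate_marginals"] = CovariateMarginals(**d["covariate_marginals"])
        for key in ("volume_range", "preference_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class TruthRecord:
    """Ground truth implied by a scenario: the conditional log-odds
    treatment effect (by construction) and marginal quantities from a
    counterfactual Monte Carlo over both potential outcomes."""

    beta_treat: float
    marginal_or: float
    marginal_rd: float
    mc_se_rd: float
    n_mc: int
    seed: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# Mean of expit(m + s*Z), Z~N(0,1), is well approximated by
# expit(m / sqrt(1 + k*s^2)) with k = 3/pi^2 * ... ~= 0.346 (probit scaling).
_LOGIT_SMOOTH = 0.346


def _linear_predictor_variance(coefs: dict[str, float], cm: CovariateMarginals) -> float:
    mom = cm.moments()
    return float(sum(coefs[name] ** 2 * mom[name][1] for name in CASE_MIX))


def _preference_logits(sc: Scenario) -> np.ndarray:
    lo, hi = sc.preference_range
    lo = max(lo, 5e-3)
    hi = min(hi, 1 - 5e-3)
    return np.linspace(logit(lo), logit(hi), sc.n_hospitals)


def _baseline_logit(sc: Scenario) -> float:
    if sc.baseline_outcome_logit is not None:
        return sc.baseline_outcome_logit
    cm = sc.covariate_marginals
    pbar = float(np.mean(expit(_preference_logits(sc))))
    var = (
        _linear_predictor_variance(sc.theta, cm)
        + sc.phi**2
        + sc.hospital_outcome_sd**2
        + (sc.hospital_outcome_pref_effect * np.std(_preference_logits(sc))) ** 2
        + sc.beta_treat**2 * pbar * (1 - pbar)
    )
    infl = np.sqrt(1 + _LOGIT_SMOOTH * var)
    return float(logit(sc.target_outcome_prevalence) * infl - sc.beta_treat * pbar)


def _hospital_structure(sc: Scenario, rng: np.random.Generator):
    """Volumes (log-uniform in range), preference logits (equally
    spaced, randomly paired to hospitals) and outcome intercepts b_h."""
    lo, hi = sc.volume_range
    volumes = np.rint(np.exp(rng.uniform(np.log(lo), np.log(hi), sc.n_hospitals)))
    volumes = np.clip(volumes, lo, hi).astype(int)
    pref = rng.permutation(_preference_logits(sc))
    pref_c = pref - pref.mean()
    # Scale alpha so the *expected* utilization matches the preference
    # target despite smoothing by patient-level logit noise.
    noise_var = _linear_predictor_variance(sc.gamma, sc.covariate_marginals) + sc.delta**2
    alpha = pref * np.sqrt(1 + _LOGIT_SMOOTH * noise_var)
    b = sc.hospital_outcome_pref_effect * pref_c + rng.normal(
        0.0, sc.hospital_outcome_sd, sc.n_hospitals
    )
    return volumes, pref, alpha, b


def _draw_covariates(
    sc: Scenario, n: int, rng: np.random.Generator, age_shift: np.ndarray | float = 0.0
) -> pd.DataFrame:
    cm = sc.covariate_marginals
    loc = cm.age_mean + np.asarray(age_shift, dtype=float)
    a = (cm.age_min - loc) / cm.age_sd
    b = (cm.age_max - loc) / cm.age_sd
    age = stats.truncnorm.rvs(a, b, loc=loc, scale=cm.age_sd, size=n, random_state=rng)
    a = (cm.nihss_min - cm.nihss_mean) / cm.nihss_sd
    b = (cm.nihss_max - cm.nihss_mean) / cm.nihss_sd
    nihss = np.rint(
        stats.truncnorm.rvs(
            a, b, loc=cm.nihss_mean, scale=cm.nihss_sd, size=n, random_state=rng
        )
    ).astype(int)
    onset = np.exp(rng.normal(np.log(cm.onset_median), cm.onset_log_sd, n))
    return pd.DataFrame(
        {
            "age": age,
            "male": rng.random(n) < cm.p_male,
            "nihss": np.clip(nihss, int(cm.nihss_min), int(cm.nihss_max)),
            "onset_to_ed_min": onset,
            "prev_stroke": rng.random(n) < cm.p_prev_stroke,
            "atrial_fib": rng.random(n) < cm.p_atrial_fib,
            "hypertension": rng.random(n) < cm.p_hypertension,
            "hypercholesterolemia": rng.random(n) < cm.p_hypercholesterolemia,
        }
    ).astype({c: int for c in ["male", "prev_stroke", "atrial_fib", "hypertension", "hypercholesterolemia"]})


def _centred(cov: pd.DataFrame, cm: CovariateMarginals) -> np.ndarray:
    mom = cm.moments()
    Xc = np.column_stack(
        [cov[name].to_numpy(dtype=float) - mom[name][0] for name in CASE_MIX]
    )
    return Xc


def _coef_vec(coefs: dict[str, float]) -> np.ndarray:
    return np.array([coefs[name] for name in CASE_MIX])


def generate_registry(
    scenario: Scenario, with_truth: bool = True, n_mc_truth: int = 100_000
) -> tuple[PatientTable, TruthRecord | None]:
    """Draw one registry from a scenario; deterministic given the seed.

    Returns the patient table and (unless ``with_truth=False``) the
    scenario's :class:`TruthRecord` from :func:`describe_truth`.
    """
    import warnings

    lo, hi = scenario.preference_range
    if hi - lo < 1e-12 and abs(scenario.beta_treat) > 0:
        warnings.warn(
            "degenerate scenario: no between-hospital preference variation; "
            "the instrument cannot identify the treatment effect",
            stacklevel=2,
        )
    rng = np.random.default_rng(scenario.seed)
    volumes, pref, alpha, b = _hospital_structure(scenario, rng)
    n = int(volumes.sum())
    hosp_idx = np.repeat(np.arange(scenario.n_hospitals), volumes)
    pref_c = pref - pref.mean()
    age_shift = scenario.hospital_age_pref_effect * pref_c[hosp_idx]
    cov = _draw_covariates(scenario, n, rng, age_shift=age_shift)
    Xc = _centred(cov, scenario.covariate_marginals)
    U = rng.normal(size=n)

    lin_t = alpha[hosp_idx] + Xc @ _coef_vec(scenario.gamma) + scenario.delta * U
    T = (rng.random(n) < expit(lin_t)).astype(int)
    beta0 = _baseline_logit(scenario)
    lin_y = (
        beta0
        + b[hosp_idx]
        + scenario.beta_treat * T
        + Xc @ _coef_vec(scenario.theta)
        + scenario.phi * U
    )
    Y = (rng.random(n) < expit(lin_y)).astype(int)

    df = pd.DataFrame(
        {
            "hospital_id": [f"H{j + 1:02d}" for j in hosp_idx],
            "treated": T,
            "good_outcome": Y,
        }
    )
    df = pd.concat([df, cov], axis=1)[COLUMNS]
    table = PatientTable(df)
    truth = None
    if with_truth:
        truth_seed = int(np.random.SeedSequence((scenario.seed, 977)).generate_state(1)[0] % (2**31))
        truth = describe_truth(scenario, n_mc=n_mc_truth, seed=truth_seed)
    return table, truth


def describe_truth(scenario: Scenario, n_mc: int = 100_000, seed: int | None = None) -> TruthRecord:
    """Counterfactual Monte Carlo oracle for the marginal estimands.

    Draws ``n_mc`` patients (allocated to hospitals proportionally to a
    volume draw), computes both potential outcome *probabilities*
    P(Y=1 | T=0) and P(Y=1 | T=1) per patient — no Bernoulli noise, so
    ``beta_treat = 0`` gives a risk difference of exactly zero — and
    averages them into the marginal risk difference and marginal odds
    ratio.
    """
    seed = scenario.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    volumes, pref, _alpha, _b = _hospital_structure(scenario, rng)
    pref_c = pref - pref.mean()
    hosp_idx = rng.choice(
        scenario.n_hospitals, size=n_mc, p=volumes / volumes.sum()
    )
    age_shift = scenario.hospital_age_pref_effect * pref_c[hosp_idx]
    cov = _draw_covariates(scenario, n_mc, rng, age_shift=age_shift)
    Xc = _centred(cov, scenario.covariate_marginals)
    U = rng.normal(size=n_mc)
    # Hospital outcome intercepts are marginalised by drawing the random
    # part fresh per patient.
    b = scenario.hospital_outcome_pref_effect * pref_c[hosp_idx] + rng.normal(
        0.0, scenario.hospital_outcome_sd, n_mc
    )
    beta0 = _baseline_logit(scenario)
    base = beta0 + b + Xc @ _coef_vec(scenario.theta) + scenario.phi * U
    p0 = expit(base)
    p1 = expit(base + scenario.beta_treat)
    rd = float(np.mean(p1 - p0))
    mc_se = float(np.std(p1 - p0, ddof=1) / np.sqrt(n_mc))
    m1, m0 = float(np.mean(p1)), float(np.mean(p0))
    or_ = (m1 / (1 - m1)) / (m0 / (1 - m0))
    return TruthRecord(
        beta_treat=scenario.beta_treat,
        marginal_or=float(or_),
        marginal_rd=rd,
        mc_se_rd=mc_se,
        n_mc=n_mc,
        seed=seed,
    )


def calibrate_beta_for_rd(
    scenario: Scenario, target_rd: float, n_mc: int = 200_000, seed: int = 12345
) -> Scenario:
    """Return a copy of the scenario with ``beta_treat`` solved (by
    bisection on the counterfactual oracle, common random numbers) so
    that the marginal risk difference equals ``target_rd``."""

    def f(beta: float) -> float:
        sc = scenario.replace(beta_treat=float(beta), baseline_outcome_logit=None)
        return describe_truth(sc, n_mc=n_mc, seed=seed).marginal_rd - target_rd

    beta = optimize.brentq(f, -4.0, 4.0, xtol=1e-6)
    return scenario.replace(beta_treat=float(beta))


# ---------------------------------------------------------------------------
# Presets


def make_ivt_like_scenario(seed: int = 0) -> Scenario:
    """Scenario emulating the intravenous-thrombolysis comparison:
    moderate between-hospital utilization variation (66-87%), sicker
    patients (older, atrial fibrillation, previous stroke, later
    arrival) *less* likely to be treated, so confounding by indication
    biases the crude odds ratio upward."""
    return Scenario(
        n_hospitals=17,
        volume_range=(23, 405),
        preference_range=(0.66, 0.87),
        beta_treat=float(np.log(1.3)),
        gamma={
            "age": -0.015,
            "male": 0.10,
            "nihss": 0.0,
            "onset_to_ed_min": -0.0015,
            "prev_stroke": -0.55,
            "atrial_fib": -1.10,
            "hypertension": -0.15,
            "hypercholesterolemia": -0.15,
        },
        theta=_OUTCOME_COEFS.copy(),
        delta=-0.5,
        phi=-0.5,
        hospital_outcome_sd=0.0,
        seed=seed,
    )


def make_ga_like_scenario(seed: int = 0) -> Scenario:
    """Scenario emulating the general-anesthesia comparison: extreme
    practice variation (essentially 0% to >90% utilization) and sicker
    patients *more* likely to be treated (delta > 0, phi < 0)."""
    return Scenario(
        n_hospitals=17,
        volume_range=(23, 405),
        preference_range=(0.005, 0.93),
        beta_treat=float(np.log(0.8)),
        gamma={
            "age": -0.010,
            "male": 0.05,
            "nihss": 0.06,
            "onset_to_ed_min": 0.0005,
            "prev_stroke": 0.0,
            "atrial_fib": 0.0,
            "hypertension": -0.20,
            "hypercholesterolemia": -0.10,
        },
        theta=_OUTCOME_COEFS.copy(),
        delta=0.5,
        phi=-0.5,
        hospital_outcome_sd=0.0,
        seed=seed,
    )


#: Outcome-model case-mix coefficients shared by both presets: worse
#: prognosis with age, stroke severity, late arrival and comorbidity.
_OUTCOME_COEFS = {
    "age": -0.045,
    "male": 0.10,
    "nihss": -0.10,
    "onset_to_ed_min": -0.0010,
    "prev_stroke": -0.30,
    "atrial_fib": -0.25,
    "hypertension": -0.15,
    "hypercholesterolemia": -0.05,
}

def make_recovery_scenario(confounded: bool = True, seed: int = 0) -> Scenario:
    """Large benchmark scenario for estimator-consistency studies:
    ~100,000 patients over 17 high-volume hospitals, a very wide
    preference range (5-95%) so nearly every patient is a "complier",
    and — when ``confounded`` — a strong unmeasured severity variable
    (delta = 0.9, phi = -0.9) that biases naive estimates downward
    while leaving the hospital-preference instrument valid.
    ``beta_treat`` is left at 0; calibrate it with
    :func:`calibrate_beta_for_rd` for a chosen true risk difference."""
    return Scenario(
        n_hospitals=17,
        volume_range=(4500, 8000),
        preference_range=(0.05, 0.95),
        delta=0.9 if confounded else 0.0,
        phi=-0.9 if confounded else 0.0,
        seed=seed,
    )


def make_dwh_null_scenario(seed: int = 0) -> Scenario:
    """Exogeneity-null scenario for Durbin-Wu-Hausman calibration:
    ~2,000 patients, measured case-mix effects as in the IVT-like
    preset but no unmeasured confounding (delta = phi = 0)."""
    ivt = make_ivt_like_scenario()
    return Scenario(
        n_hospitals=17,
        volume_range=(60, 180),
        preference_range=(0.2, 0.8),
        beta_treat=float(np.log(1.3)),
        gamma=ivt.gamma,
        theta=ivt.theta,
        delta=0.0,
        phi=0.0,
        seed=seed,
    )


def make_invalid_instrument_scenario(seed: int = 0) -> Scenario:
    """Negative-control scenario: IVT-like confounding plus deliberate
    instrument invalidation — hospital outcome level and hospital mean
    age both correlated with the preference logit, violating the
    exclusion restriction and the no-confounder-association
    assumption.  Volumes are scaled up for stable hospital-level
    estimates."""
    sc = make_ivt_like_scenario(seed=seed)
    return sc.replace(
        volume_range=(600, 1800),
        hospital_outcome_pref_effect=0.8,
        hospital_age_pref_effect=5.0,
    )


PRESETS = {
    "ivt_like": make_ivt_like_scenario,
    "ga_like": make_ga_like_scenario,
    "recovery": make_recovery_scenario,
    "dwh_null": make_dwh_null_scenario,
    "invalid_instrument": make_invalid_instrument_scenario,
}
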