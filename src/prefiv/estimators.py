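"""Treatment-effect estimators and instrument diagnostics.

Five estimation approaches for the effect of a binary treatment on a
binary outcome in a clustered registry, each unadjusted or adjusted for
the eight case-mix covariates:

* individual-level logistic regression (odds-ratio scale),
* GEE with exchangeable working correlation (odds-ratio scale),
* hospital-level ecological weighted linear regression (percentage
  points of outcome per percentage point of utilization),
* two-stage predictor-substitution IV with a logistic first and second
  stage (odds ratio per unit predicted treatment probability), and
* linear two-stage least squares (risk-difference scale).

The instrument is the hospital's treatment preference: the proportion
of that hospital's patients who received the treatment (plain, or a
leave-one-out variant).  Validity diagnostics cover instrument strength
(first-stage partial R-squared and the F-statistic
[R2 (n - 1 - K)] / [(1 - R2) K]), endogeneity (Durbin-Wu-Hausman test
in control-function form) and instrument/case-mix associations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import glm
from .registry import CASE_MIX, HOSPITAL_CASE_MIX, PatientTable, aggregate_by_hospital

Z95 = float(stats.norm.ppf(0.975))


class EstimationError(RuntimeError):
    """The requested estimator is not identified on this table."""


@dataclass
class EstimateResult:
    """One method's treatment-effect estimate on its native scale."""

    method: str  # logistic | gee | ecological | iv_two_stage | iv_linear
    adjusted: bool
    scale: str  # odds_ratio | percentage_point_per_1pct | risk_difference
    estimate: float
    ci_low: float
    ci_high: float
    se: float  # on the estimation (log-odds / slope / rd) scale
    n_patients: int
    n_hospitals: int
    flags: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence interval must bracket the estimate")
        if self.scale == "odds_ratio" and self.estimate <= 0:
            raise ValueError("odds-ratio estimates must be positive")


@dataclass
class InstrumentVector:
    """Per-patient hospital-preference instrument values in [0, 1]."""

    values: np.ndarray
    leave_one_out: bool

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any((v < 0) | (v > 1)):
            raise ValueError("instrument values must lie in [0, 1]")
        self.values = v


@dataclass
class IVDiagnostics:
    """Instrument-validity diagnostics.

    ``confounder_assoc`` is a per-covariate table of volume-weighted
    hospital-level regressions of the covariate on the instrument.
    """

    partial_r2: float
    f_statistic: float
    f_n: int
    f_k: int
    dwh_statistic: float
    dwh_p: float
    confounder_assoc: pd.DataFrame
    strength_ok: bool
    endogeneity_detected: bool
    instrument_confounder_assoc_detected: bool


# ---------------------------------------------------------------------------
# design-matrix helpers


def _design(df: pd.DataFrame, cols: list[str]) -> tuple[np.ndarray, list[str]]:
    X = np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in cols]
    )
    return X, ["intercept"] + list(cols)


def _wald(coef: float, se: float) -> tuple[float, float]:
    return coef - Z95 * se, coef + Z95 * se


def _require_hospitals(table: PatientTable, k: int, what: str) -> None:
    if table.n_hospitals < k:
        raise EstimationError(f"{what} requires at least {k} hospitals")


# ---------------------------------------------------------------------------
# individual-level estimators


def estimate_individual_logistic(table: PatientTable, adjusted: bool) -> EstimateResult:
    """Logistic regression of good outcome on treatment (plus case-mix
    when adjusted); Wald 95% CI on the log-odds scale."""
    cols = ["treated"] + (CASE_MIX if adjusted else [])
    X, names = _design(table.df, cols)
    fit = glm.fit_logistic(X, table.df["good_outcome"].to_numpy(), names=names)
    b, se = fit.coef[1], fit.se()[1]
    lo, hi = _wald(b, se)
    return EstimateResult(
        method="logistic",
        adjusted=adjusted,
        scale="odds_ratio",
        estimate=float(np.exp(b)),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        se=float(se),
        n_patients=table.n_patients,
        n_hospitals=table.n_hospitals,
        extra={"rd_estimate": _logistic_ame(fit, X, 1), "log_or": float(b)},
    )


def estimate_gee(table: PatientTable, adjusted: bool) -> EstimateResult:
    """GEE logistic regression with exchangeable within-hospital working
    correlation; robust (sandwich) standard errors."""
    _require_hospitals(table, 2, "GEE")
    cols = ["treated"] + (CASE_MIX if adjusted else [])
    X, names = _design(table.df, cols)
    fit = glm.fit_gee_logistic_exchangeable(
        X, table.df["good_outcome"].to_numpy(), table.df["hospital_id"], names=names
    )
    b, se = fit.coef[1], fit.se(robust=True)[1]
    lo, hi = _wald(b, se)
    return EstimateResult(
        method="gee",
        adjusted=adjusted,
        scale="odds_ratio",
        estimate=float(np.exp(b)),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        se=float(se),
        n_patients=table.n_patients,
        n_hospitals=table.n_hospitals,
        flags={"converged": fit.converged},
        extra={"rho": float(fit.rho), "rd_estimate": _logistic_ame(fit, X, 1), "log_or": float(b)},
    )


def _logistic_ame(fit: glm.FitResult, X: np.ndarray, treat_col: int) -> float:
    """Average marginal effect of the treatment column: mean difference
    of fitted probabilities with the column forced to 1 versus 0."""
    from scipy.special import expit

    X1 = X.copy()
    X0 = X.copy()
    X1[:, treat_col] = 1.0
    X0[:, treat_col] = 0.0
    return float(np.mean(expit(X1 @ fit.coef) - expit(X0 @ fit.coef)))


# ---------------------------------------------------------------------------
# ecological (hospital-level) estimator


def estimate_ecological(table: PatientTable, adjusted: bool) -> EstimateResult:
    """Volume-weighted linear regression of the hospital's percent good
    outcome on its percent treated (plus hospital-level case-mix means
    when adjusted).  The slope is the change in absolute outcome
    probability, in percentage points, per additional 1% utilization."""
    hosp = aggregate_by_hospital(table)
    cols = ["pct_treated"] + (HOSPITAL_CASE_MIX if adjusted else [])
    n_params = len(cols) + 1
    if len(hosp) < max(3, n_params + 1):
        raise EstimationError(
            f"ecological regression with {n_params} parameters needs more than "
            f"{len(hosp)} hospitals"
        )
    if np.isclose(hosp["pct_treated"].var(), 0.0):
        raise EstimationError("utilization is identical across hospitals; slope unidentified")
    if len(hosp) < 2 * n_params:
        warnings.warn(
            f"ecological regression fits {n_params} parameters on only "
            f"{len(hosp)} hospital-level observations",
            stacklevel=2,
        )
    X, names = _design(hosp, cols)
    fit = glm.fit_wls(
        X, hosp["pct_good_outcome"].to_numpy(), hosp["n_patients"].to_numpy(), names=names
    )
    b, se = fit.coef[1], fit.se()[1]
    lo, hi = _wald(b, se)
    return EstimateResult(
        method="ecological",
        adjusted=adjusted,
        scale="percentage_point_per_1pct",
        estimate=float(b),
        ci_low=float(lo),
        ci_high=float(hi),
        se=float(se),
        n_patients=table.n_patients,
        n_hospitals=table.n_hospitals,
        extra={"rd_estimate": float(b)},  # pp-per-pp slope is dimensionless
    )


# ---------------------------------------------------------------------------
# instrument construction and IV estimators


def build_instrument(table: PatientTable, leave_one_out: bool = False) -> InstrumentVector:
    """Hospital-preference instrument: the proportion of each
    hospital's patients who received the treatment.

    The plain variant assigns every patient of hospital h the same
    proportion pi_h; the leave-one-out variant excludes the patient's
    own treatment, removing mechanical own-observation correlation."""
    df = table.df
    counts = df.groupby("hospital_id", sort=False)["treated"].transform("sum")
    sizes = df.groupby("hospital_id", sort=False)["treated"].transform("size")
    if leave_one_out:
        if (sizes < 2).any():
            raise EstimationError("leave-one-out instrument undefined for 1-patient hospitals")
        vals = (counts - df["treated"]) / (sizes - 1)
    else:
        vals = counts / sizes
    return InstrumentVector(values=vals.to_numpy(dtype=float), leave_one_out=leave_one_out)


def _volume_covariate(table: PatientTable) -> np.ndarray:
    sizes = table.df.groupby("hospital_id", sort=False)["treated"].transform("size")
    return sizes.to_numpy(dtype=float) / 100.0  # per 100 patients, keeps coefficients O(1)


def _iv_frame(table: PatientTable, instrument: InstrumentVector, adjusted: bool):
    df = table.df.copy()
    df["_instrument"] = instrument.values
    cols = ["_instrument"]
    if adjusted:
        df["_volume"] = _volume_covariate(table)
        cols += CASE_MIX + ["_volume"]
    return df, cols


def estimate_iv_two_stage(
    table: PatientTable,
    adjusted: bool,
    instrument: InstrumentVector | None = None,
    ci: str = "bootstrap",
    n_boot: int = 500,
    seed: int = 0,
) -> EstimateResult:
    """Two-stage predictor-substitution IV estimator.

    Stage 1: logistic regression of treatment on the hospital-preference
    instrument (plus case-mix and hospital volume when adjusted).
    Stage 2: logistic regression of outcome on the stage-1 predicted
    probability (plus case-mix).  The effect is the odds ratio per unit
    predicted probability, i.e. moving from 0% to 100% probability of
    treatment.  The default CI resamples hospitals (cluster bootstrap);
    ``ci="analytic"`` uses the hospital-cluster sandwich on stage 2,
    which ignores stage-1 uncertainty.

    A first-stage F below 10 flags ``strength_ok=False`` in the result,
    never silently.
    """
    _require_hospitals(table, 2, "instrumental-variable estimation")
    if instrument is None:
        instrument = build_instrument(table)
    if np.isclose(np.var(instrument.values), 0.0):
        raise EstimationError("instrument is constant across hospitals")
    b, se_an, fit2, X2 = _two_stage_coef(table, instrument, adjusted)

    diag = iv_diagnostics(table, instrument, adjusted)
    flags = {"strength_ok": diag.strength_ok, "ci": ci}
    if ci == "bootstrap":
        rng = np.random.default_rng(seed)
        hospitals = table.hospitals
        boots = []
        failures = 0
        df = table.df
        blocks = {h: df[df["hospital_id"] == h] for h in hospitals}
        for _ in range(n_boot):
            chosen = rng.choice(hospitals, size=len(hospitals), replace=True)
            parts = []
            for j, h in enumerate(chosen):
                part = blocks[h].copy()
                part["hospital_id"] = f"B{j:02d}"  # resampled copies are distinct clusters
                parts.append(part)
            bt = PatientTable(pd.concat(parts, ignore_index=True))
            try:
                binst = build_instrument(bt, leave_one_out=instrument.leave_one_out)
                bb, *_ = _two_stage_coef(bt, binst, adjusted)
                boots.append(bb)
            except (glm.GlmError, EstimationError):
                failures += 1
        boots = np.asarray(boots)
        if len(boots) < max(20, n_boot // 2):
            raise EstimationError(
                f"cluster bootstrap failed in {failures}/{n_boot} replicates"
            )
        se = float(np.std(boots, ddof=1))
        lo, hi = np.percentile(boots, [2.5, 97.5])
        lo, hi = min(lo, b), max(hi, b)  # percentile CI may not bracket the point estimate
        flags["n_boot_ok"] = int(len(boots))
    else:
        se = se_an
        lo, hi = _wald(b, se)
    return EstimateResult(
        method="iv_two_stage",
        adjusted=adjusted,
        scale="odds_ratio",
        estimate=float(np.exp(b)),
        ci_low=float(np.exp(lo)),
        ci_high=float(np.exp(hi)),
        se=float(se),
        n_patients=table.n_patients,
        n_hospitals=table.n_hospitals,
        flags=flags,
        extra={
            "rd_estimate": _logistic_ame(fit2, X2, 1),
            "partial_r2": diag.partial_r2,
            "f_statistic": diag.f_statistic,
            "log_or": float(b),
        },
    )


def _two_stage_coef(table: PatientTable, instrument: InstrumentVector, adjusted: bool):
    df, cols1 = _iv_frame(table, instrument, adjusted)
    X1, names1 = _design(df, cols1)
    fit1 = glm.fit_logistic(X1, df["treated"].to_numpy(), names=names1)
    df["_phat"] = fit1.fitted
    cols2 = ["_phat"] + (CASE_MIX if adjusted else [])
    X2, names2 = _design(df, cols2)
    fit2 = glm.fit_logistic(X2, df["good_outcome"].to_numpy(), names=names2)
    cov = glm.cluster_robust_covariance(
        fit2, X2, df["good_outcome"].to_numpy(), df["hospital_id"]
    )
    return float(fit2.coef[1]), float(np.sqrt(cov[1, 1])), fit2, X2


def estimate_iv_linear(
    table: PatientTable,
    adjusted: bool,
    instrument: InstrumentVector | None = None,
) -> EstimateResult:
    """Linear two-stage least squares on the probability scale.

    Stage 1 projects treatment on the instrument (plus covariates);
    stage 2 regresses the outcome on the fitted treatment (plus the
    same covariates).  The estimate is a risk difference.  Standard
    errors are the proper 2SLS hospital-cluster sandwich (residuals
    formed with the *observed* treatment)."""
    _require_hospitals(table, 2, "instrumental-variable estimation")
    if instrument is None:
        instrument = build_instrument(table)
    if np.isclose(np.var(instrument.values), 0.0):
        raise EstimationError("instrument is constant across hospitals")
    df, cols1 = _iv_frame(table, instrument, adjusted)
    exog = CASE_MIX if adjusted else []
    y = df["good_outcome"].to_numpy(dtype=float)
    t = df["treated"].to_numpy(dtype=float)

    Xz, _ = _design(df, cols1)  # instrument + exogenous covariates (+ volume)
    glm.check_design(Xz)
    that, *_ = np.linalg.lstsq(Xz, t, rcond=None)
    t_fit = Xz @ that

    W = np.column_stack([np.ones(len(df)), t] + [df[c].to_numpy(float) for c in exog])
    What = W.copy()
    What[:, 1] = t_fit
    names = ["intercept", "treated"] + exog
    glm.check_design(What, names)
    beta = np.linalg.solve(What.T @ What, What.T @ y)
    resid = y - W @ beta  # structural residuals use observed treatment

    ids, inv = np.unique(df["hospital_id"].to_numpy(), return_inverse=True)
    G = len(ids)
    S = np.zeros((G, What.shape[1]))
    np.add.at(S, inv, What * resid[:, None])
    bread = np.linalg.inv(What.T @ What)
    cov = (G / (G - 1)) * bread @ (S.T @ S) @ bread

    b, se = float(beta[1]), float(np.sqrt(cov[1, 1]))
    lo, hi = _wald(b, se)
    diag = iv_diagnostics(table, instrument, adjusted)
    return EstimateResult(
        method="iv_linear",
        adjusted=adjusted,
        scale="risk_difference",
        estimate=b,
        ci_low=float(lo),
        ci_high=float(hi),
        se=se,
        n_patients=table.n_patients,
        n_hospitals=table.n_hospitals,
        flags={"strength_ok": diag.strength_ok},
        extra={
            "rd_estimate": b,
            "partial_r2": diag.partial_r2,
            "f_statistic": diag.f_statistic,
        },
    )


# ---------------------------------------------------------------------------
# diagnostics


def f_statistic(partial_r2: float, n: int, k: int = 1) -> float:
    """Instrument-strength F-statistic, [R2 (n - 1 - K)] / [(1 - R2) K],
    where R2 is the first-stage partial R-squared, n the sample size and
    K the number of instruments."""
    return (partial_r2 * (n - 1 - k)) / ((1 - partial_r2) * k)


def _ols_r2(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = float(np.sum((y - y.mean()) ** 2))
    return (1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 0.0), resid


def iv_diagnostics(
    table: PatientTable, instrument: InstrumentVector, adjusted: bool
) -> IVDiagnostics:
    """Screen the three IV assumptions.

    * Strength: partial R-squared of the instrument in a linear first
      stage (increment in R2 over the covariate-only model) and the
      F-statistic with K = 1; rule of thumb F > 10.
    * Endogeneity: Durbin-Wu-Hausman in control-function form — the
      linear first-stage residual is added to a linear outcome model
      and its Wald statistic (heteroskedasticity-robust) is referred to
      chi-squared with 1 df.
    * Exchangeability proxy: volume-weighted hospital-level regressions
      of each case-mix covariate on the instrument; any p < 0.05 raises
      the association flag (raw p-values, no multiplicity correction).
    """
    df, cols1 = _iv_frame(table, instrument, adjusted)
    y = df["good_outcome"].to_numpy(dtype=float)
    t = df["treated"].to_numpy(dtype=float)
    n = len(df)

    X_full, _ = _design(df, cols1)
    X_red, _ = _design(df, cols1[1:])  # drop the instrument
    r2_full, resid1 = _ols_r2(X_full, t)
    r2_red, _ = _ols_r2(X_red, t)
    partial_r2 = max(r2_full - r2_red, 0.0)
    K = 1
    f_stat = f_statistic(partial_r2, n, K)

    # DWH control-function test
    exog = CASE_MIX if adjusted else []
    A = np.column_stack(
        [np.ones(n), t] + [df[c].to_numpy(float) for c in exog] + [resid1]
    )
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    u = y - A @ beta
    bread = np.linalg.inv(A.T @ A)
    meat = A.T @ (A * (u**2)[:, None])
    hc1 = n / max(n - A.shape[1], 1)
    cov = hc1 * bread @ meat @ bread
    j = A.shape[1] - 1
    dwh = float(beta[j] ** 2 / cov[j, j])
    dwh_p = float(stats.chi2.sf(dwh, df=1))

    # instrument vs case-mix, hospital level, volume weighted
    hosp = aggregate_by_hospital(table)
    pi = hosp["pct_treated"].to_numpy() / 100.0
    Xh = np.column_stack([np.ones(len(hosp)), pi])
    rows = []
    for raw, agg in zip(CASE_MIX, HOSPITAL_CASE_MIX):
        fit = glm.fit_wls(Xh, hosp[agg].to_numpy(float), hosp["n_patients"].to_numpy(float))
        est, se = fit.coef[1], fit.se()[1]
        tval = est / se if se > 0 else np.inf
        p = 2 * stats.t.sf(abs(tval), df=max(len(hosp) - 2, 1))
        rows.append({"covariate": raw, "estimate": float(est), "se": float(se), "p": float(p)})
    assoc = pd.DataFrame(rows)

    return IVDiagnostics(
        partial_r2=float(partial_r2),
        f_statistic=float(f_stat),
        f_n=n,
        f_k=K,
        dwh_statistic=dwh,
        dwh_p=dwh_p,
        confounder_assoc=assoc,
        strength_ok=bool(f_stat > 10),
        endogeneity_detected=bool(dwh_p < 0.05),
        instrument_confounder_assoc_detected=bool((assoc["p"] < 0.05).any()),
    )
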