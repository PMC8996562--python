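"""Numerical core: IRLS logistic regression, weighted least squares,
cluster-robust sandwich covariance, and GEE for binary outcomes with an
exchangeable (compound-symmetry) working correlation.

All fitters take a plain design matrix (rows = patients, columns =
terms including the intercept) and return a :class:`FitResult` holding
coefficients, a model-based covariance and convergence metadata.
Cluster-robust ("sandwich") covariances sum score contributions within
clusters and apply the G/(G-1) small-sample factor, G being the number
of clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy.special import expit


class GlmError(RuntimeError):
    """Base class for fitting failures."""


class RankDeficiencyError(GlmError):
    """The design matrix is not of full column rank."""


class SeparationError(GlmError):
    """The logistic likelihood has no finite maximiser (perfect or
    quasi-perfect separation, or a degenerate response)."""


class ClusterError(GlmError):
    """Clustered covariance requested with fewer than two clusters."""


#: A coefficient exceeding this magnitude on the standardised scale is
#: taken as evidence of separation (divergence of the MLE).
SEPARATION_THRESHOLD = 30.0


def check_design(X: np.ndarray, names: list[str] | None = None) -> None:
    """Require a finite, full-column-rank design; name the dependent
    columns on failure."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise GlmError("design matrix contains non-finite entries")
    n, p = X.shape
    _, r, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(n, p) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int(np.sum(diag > tol))
    if rank < p:
        bad = sorted(piv[rank:])
        labels = [names[j] if names else f"column {j}" for j in bad]
        raise RankDeficiencyError(
            f"design matrix is rank deficient; collinear term(s): {', '.join(map(str, labels))}"
        )


@dataclass
class FitResult:
    """One fitted regression model.

    ``cov`` is the model-based covariance of the coefficients;
    ``robust_cov`` is filled in by :func:`cluster_robust_covariance`.
    ``bread`` is the unscaled inverse information used by the sandwich.
    """

    coef: np.ndarray
    cov: np.ndarray
    names: list[str]
    converged: bool
    n_iter: int
    kind: str  # 'logistic' | 'wls'
    fitted: np.ndarray
    prior_weights: np.ndarray
    bread: np.ndarray
    llf: float | None = None
    robust_cov: np.ndarray | None = None

    @property
    def residuals(self) -> np.ndarray:
        """Response-scale residuals y - fitted mean."""
        return self._y - self.fitted

    def se(self, robust: bool = False) -> np.ndarray:
        c = self.robust_cov if robust else self.cov
        if c is None:
            raise ValueError("robust covariance has not been computed")
        return np.sqrt(np.diag(c))

    _y: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


@dataclass
class GEEFit(FitResult):
    rho: float = 0.0
    phi: float = 1.0


def _loglik(y, p, w):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(w * (y * np.log(p) + (1 - y) * np.log1p(-p))))


def _separation_check(beta: np.ndarray, scales: np.ndarray) -> None:
    if np.any(np.abs(beta) * scales > SEPARATION_THRESHOLD):
        raise SeparationError(
            "coefficients diverging (|standardised coefficient| > "
            f"{SEPARATION_THRESHOLD:g}): perfect separation or degenerate response"
        )


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    names: list[str] | None = None,
    max_iter: int = 100,
    score_tol: float = 1e-8,
    coef_tol: float = 1e-10,
) -> FitResult:
    """Maximum-likelihood logistic regression by iteratively reweighted
    least squares (Newton scoring) with step-halving.

    Converges when the maximal absolute score falls below ``score_tol``
    or the maximal coefficient change below ``coef_tol``; the
    log-likelihood is nondecreasing across iterations by construction.
    Raises :class:`SeparationError` when the MLE diverges and
    :class:`RankDeficiencyError` on a collinear design.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise GlmError("response must be coded 0/1")
    if np.all(y == y[0]):
        raise SeparationError("degenerate response: all outcomes equal, MLE diverges")
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise GlmError("weights must be nonnegative")
    names = names or [f"x{j}" for j in range(X.shape[1])]
    check_design(X, names)

    scales = X.std(axis=0)
    scales[scales == 0] = 1.0  # constant columns judged on the raw scale

    beta = np.zeros(X.shape[1])
    ll = _loglik(y, np.full_like(y, 0.5), w)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        p = expit(X @ beta)
        score = X.T @ (w * (y - p))
        if np.max(np.abs(score)) < score_tol:
            converged = True
            break
        wirls = np.maximum(w * p * (1 - p), 1e-12)
        H = X.T @ (X * wirls[:, None])
        try:
            delta = np.linalg.solve(H, score)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded above
            raise RankDeficiencyError(str(exc)) from exc
        step = 1.0
        for _ in range(40):  # step-halving: never let the log-likelihood drop
            beta_new = beta + step * delta
            ll_new = _loglik(y, expit(X @ beta_new), w)
            if ll_new >= ll - 1e-12:
                break
            step /= 2.0
        change = np.max(np.abs(beta_new - beta))
        beta, ll = beta_new, ll_new
        _separation_check(beta, scales)
        if change < coef_tol:
            converged = True
            break

    p = expit(X @ beta)
    wirls = np.maximum(w * p * (1 - p), 1e-12)
    H = X.T @ (X * wirls[:, None])
    bread = np.linalg.inv(H)
    return FitResult(
        coef=beta,
        cov=bread,
        names=names,
        converged=converged,
        n_iter=n_iter,
        kind="logistic",
        fitted=p,
        prior_weights=w,
        bread=bread,
        llf=_loglik(y, p, w),
        _y=y,
    )


def fit_wls(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    names: list[str] | None = None,
) -> FitResult:
    """Weighted least squares, minimising sum_i w_i (y_i - x_i'beta)^2
    via the QR-based normal-equations solution."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise GlmError("weights must be nonnegative")
    if not np.any(w > 0):
        raise GlmError("weights must not be all zero")
    names = names or [f"x{j}" for j in range(X.shape[1])]
    sw = np.sqrt(w)
    check_design(X * sw[:, None], names)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    fitted = X @ beta
    resid = y - fitted
    n_used = int(np.sum(w > 0))
    dof = max(n_used - X.shape[1], 1)
    sigma2 = float(np.sum(w * resid**2)) / dof
    bread = np.linalg.inv(X.T @ (X * w[:, None]))
    return FitResult(
        coef=beta,
        cov=sigma2 * bread,
        names=names,
        converged=True,
        n_iter=0,
        kind="wls",
        fitted=fitted,
        prior_weights=w,
        bread=bread,
        _y=y,
    )


def _score_contributions(fit: FitResult, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    # For both the logistic and the weighted-linear model the per-row
    # estimating-function contribution is w_i * x_i * (y_i - mu_i).
    return X * (fit.prior_weights * (np.asarray(y, float) - fit.fitted))[:, None]


def cluster_robust_covariance(
    fit: FitResult, X: np.ndarray, y: np.ndarray, cluster_ids
) -> np.ndarray:
    """Cluster-robust sandwich covariance with the G/(G-1) small-sample
    factor.  With every row its own cluster this reduces to the
    heteroskedasticity-robust sandwich times n/(n-1)."""
    X = np.asarray(X, dtype=float)
    ids, inv = np.unique(np.asarray(cluster_ids), return_inverse=True)
    G = len(ids)
    if G < 2:
        raise ClusterError("cluster-robust covariance requires at least 2 clusters")
    s = _score_contributions(fit, X, y)
    S = np.zeros((G, X.shape[1]))
    np.add.at(S, inv, s)
    meat = S.T @ S
    cov = (G / (G - 1)) * fit.bread @ meat @ fit.bread
    fit.robust_cov = cov
    return cov


def fit_gee_logistic_exchangeable(
    X: np.ndarray,
    y: np.ndarray,
    cluster_ids,
    names: list[str] | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> GEEFit:
    """GEE for a binary outcome with logit link and exchangeable
    working correlation.

    Alternates a generalized-least-squares coefficient update (using the
    closed-form inverse of the compound-symmetry correlation matrix)
    with a method-of-moments update of the common within-cluster
    correlation rho from standardised Pearson residuals, with the
    N_pairs - p denominator.  The reported covariance is the
    cluster-robust sandwich; the model-based one is phi * bread.
    Non-convergence returns a partial result flagged
    ``converged=False``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    ids, inv = np.unique(np.asarray(cluster_ids), return_inverse=True)
    G = len(ids)
    if G < 2:
        raise ClusterError("GEE requires at least 2 clusters")
    names = names or [f"x{j}" for j in range(X.shape[1])]

    order = np.argsort(inv, kind="stable")
    Xs, ys = X[order], y[order]
    sizes = np.bincount(inv)
    bounds = np.concatenate(([0], np.cumsum(sizes)))
    n, p = X.shape
    n_pairs = int(np.sum(sizes * (sizes - 1) // 2))
    max_size = int(sizes.max())

    start = fit_logistic(X, y, names=names)
    beta = start.coef.copy()
    rho = 0.0
    phi = 1.0
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mu = np.clip(expit(Xs @ beta), 1e-10, 1 - 1e-10)
        a = mu * (1 - mu)
        e = (ys - mu) / np.sqrt(a)
        phi = float(np.sum(e**2)) / max(n - p, 1)
        if n_pairs > 0:
            csum = np.zeros(G)
            csum_sq = np.zeros(G)
            np.add.at(csum, inv[order], e)
            np.add.at(csum_sq, inv[order], e**2)
            cross = float(np.sum(csum**2 - csum_sq)) / 2.0
            rho = cross / (phi * max(n_pairs - p, 1))
            lb = -1.0 / (max_size - 1) if max_size > 1 else -0.99
            rho = float(np.clip(rho, lb + 1e-6, 0.99))
        else:
            rho = 0.0

        H = np.zeros((p, p))
        gvec = np.zeros(p)
        sqa = np.sqrt(a)
        for g in range(G):
            lo, hi = bounds[g], bounds[g + 1]
            m = hi - lo
            B = Xs[lo:hi] * sqa[lo:hi, None]
            eg = e[lo:hi]
            c = rho / (1.0 + (m - 1) * rho)
            # R^{-1} M = (M - c * 1 1'M) / (1 - rho)
            colsum = B.sum(axis=0)
            RinvB = (B - c * colsum[None, :]) / (1.0 - rho)
            H += B.T @ RinvB
            gvec += RinvB.T @ eg
        try:
            delta = np.linalg.solve(H, gvec)
        except np.linalg.LinAlgError as exc:
            raise RankDeficiencyError(str(exc)) from exc
        beta = beta + delta
        if np.max(np.abs(delta)) < tol:
            converged = True
            break

    # Sandwich covariance at the solution.
    mu = np.clip(expit(Xs @ beta), 1e-10, 1 - 1e-10)
    a = mu * (1 - mu)
    e = (ys - mu) / np.sqrt(a)
    sqa = np.sqrt(a)
    H = np.zeros((p, p))
    meat = np.zeros((p, p))
    for g in range(G):
        lo, hi = bounds[g], bounds[g + 1]
        m = hi - lo
        B = Xs[lo:hi] * sqa[lo:hi, None]
        c = rho / (1.0 + (m - 1) * rho)
        colsum = B.sum(axis=0)
        RinvB = (B - c * colsum[None, :]) / (1.0 - rho)
        H += B.T @ RinvB
        u = RinvB.T @ e[lo:hi]
        meat += np.outer(u, u)
    bread = np.linalg.inv(H)
    robust = (G / (G - 1)) * bread @ meat @ bread

    fitted = expit(X @ beta)
    return GEEFit(
        coef=beta,
        cov=phi * bread,
        names=names,
        converged=converged,
        n_iter=n_iter,
        kind="logistic",
        fitted=fitted,
        prior_weights=np.ones(n),
        bread=bread,
        robust_cov=robust,
        rho=rho,
        phi=phi,
        _y=y,
    )
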