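"""Shared statistical primitives for NTCP model development.

Everything downstream — univariable screening, bootstrap-LASSO selection,
cross-validated model comparison, the penalized final fit — is built on the
routines here: maximum-likelihood and L1-penalized logistic regression, the
logistic NTCP transform, AUC-ROC, cross-entropy, information criteria, the
Hosmer–Lemeshow calibration test, Spearman rank correlation and contingency
tests.

The logistic model is

    NTCP = 1 / (1 + exp(-(b0 + b1*x1 + ... + bn*xn)))

with ``b0`` the offset and ``bi`` the coefficient of covariate ``xi``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

__all__ = [
    "DegenerateFitError",
    "FittedLogisticModel",
    "MetricSet",
    "fit_logistic",
    "fit_logistic_lasso",
    "lasso_lambda_for_max_k",
    "lasso_path_lambdas",
    "ntcp",
    "predict_proba",
    "auc_roc",
    "cross_entropy",
    "aic_bic",
    "hosmer_lemeshow",
    "spearman_rcc",
    "chi_square_test",
    "rank_sum_test",
    "fisher_exact_test",
]

# numerical guards
_PROB_CLIP = 1e-12        # probability clipping for cross-entropy
_WEIGHT_FLOOR = 1e-6      # IRLS weight floor
_BETA_BOUND = 15.0        # |beta| beyond this flags quasi-separation
_ZERO_COEF = 1e-8         # a standardized slope below this is "not selected"


class DegenerateFitError(ValueError):
    """Raised when a logistic fit is impossible (e.g. single-class outcomes)."""


@dataclass
class FittedLogisticModel:
    """A fitted binomial-logit model.

    ``beta`` holds the offset first, then one coefficient per entry of
    ``covariate_names``, all on the original covariate scale.  For penalized
    fits ``beta_std`` additionally holds the coefficients on the internally
    standardized scale (that is the scale on which selection decisions are
    made).
    """

    covariate_names: list[str]
    beta: np.ndarray
    log_likelihood: float
    n_obs: int
    n_params: int
    penalized: bool = False
    lam: float = 0.0
    converged: bool = True
    standard_errors: np.ndarray | None = None
    p_values: np.ndarray | None = None
    beta_std: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.beta) != len(self.covariate_names) + 1:
            raise ValueError("beta must have one entry per covariate plus the offset")

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.beta[0] + X @ self.beta[1:]

    def n_nonzero_slopes(self) -> int:
        ref = self.beta_std[1:] if self.beta_std is not None else self.beta[1:]
        return int(np.sum(np.abs(ref) > _ZERO_COEF))

    def to_dict(self) -> dict:
        return {
            "covariate_names": list(self.covariate_names),
            "beta": self.beta.tolist(),
            "log_likelihood": self.log_likelihood,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "penalized": self.penalized,
            "lambda": self.lam,
            "converged": self.converged,
        }


@dataclass
class MetricSet:
    """The five model-comparison metrics used throughout the pipeline."""

    auc_roc: float
    cross_entropy: float
    aic: float
    bic: float
    hl_statistic: float
    hl_pvalue: float

    def to_dict(self) -> dict:
        return {
            "auc_roc": self.auc_roc,
            "cross_entropy": self.cross_entropy,
            "aic": self.aic,
            "bic": self.bic,
            "hl_statistic": self.hl_statistic,
            "hl_pvalue": self.hl_pvalue,
        }


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-eta))


def _log_likelihood(eta: np.ndarray, y: np.ndarray) -> float:
    # numerically stable Bernoulli log-likelihood: y*eta - log(1+exp(eta))
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _check_xy(X, y) -> tuple[np.ndarray, np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("design matrix and outcome vector disagree in length")
    classes = np.unique(y)
    if not np.all(np.isin(classes, [0.0, 1.0])):
        raise ValueError("outcomes must be binary 0/1")
    if classes.size < 2:
        raise DegenerateFitError("outcomes contain a single class; logistic fit is degenerate")
    return X, y


def fit_logistic(
    design: np.ndarray,
    outcomes: np.ndarray,
    covariate_names: Sequence[str] | None = None,
    *,
    max_iter: int = 100,
    tol: float = 1e-9,
    beta_bound: float = _BETA_BOUND,
) -> FittedLogisticModel:
    """Maximum-likelihood logistic regression via iteratively reweighted
    least squares.

    Convergence is declared when the relative change in log-likelihood falls
    below ``tol`` within ``max_iter`` iterations.  Quasi-separation
    (any |coefficient| exceeding ``beta_bound``) sets ``converged=False``
    rather than raising, so resampling loops survive degenerate draws.
    Standard errors come from the observed information matrix and Wald
    p-values are attached per coefficient.
    """
    X, y = _check_xy(design, outcomes)
    n, p = X.shape
    if covariate_names is None:
        covariate_names = [f"x{i + 1}" for i in range(p)]
    if n <= p + 1:
        raise DegenerateFitError(f"n_obs={n} must exceed n_params={p + 1}")

    Xd = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    prev = y.mean()
    beta[0] = math.log(prev / (1.0 - prev))
    ll_old = _log_likelihood(Xd @ beta, y)
    converged = False
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = _sigmoid(eta)
        w = np.clip(mu * (1.0 - mu), _WEIGHT_FLOOR, None)
        z = eta + (y - mu) / w
        WX = Xd * w[:, None]
        try:
            beta = np.linalg.solve(Xd.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError:
            converged = False
            break
        ll = _log_likelihood(Xd @ beta, y)
        if np.max(np.abs(beta)) > beta_bound:
            converged = False
            break
        if abs(ll - ll_old) < tol * (abs(ll_old) + tol):
            converged = True
            ll_old = ll
            break
        ll_old = ll

    eta = Xd @ beta
    mu = _sigmoid(eta)
    w = np.clip(mu * (1.0 - mu), _WEIGHT_FLOOR, None)
    info = Xd.T @ (Xd * w[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        zscores = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
        pvals = 2.0 * sps.norm.sf(np.abs(zscores))
    except np.linalg.LinAlgError:
        se = np.full(p + 1, np.nan)
        pvals = np.full(p + 1, np.nan)

    return FittedLogisticModel(
        covariate_names=list(covariate_names),
        beta=beta,
        log_likelihood=_log_likelihood(eta, y),
        n_obs=n,
        n_params=p + 1,
        penalized=False,
        lam=0.0,
        converged=converged,
        standard_errors=se,
        p_values=pvals,
    )


# ---------------------------------------------------------------------------
# L1-penalized logistic regression (coordinate descent on the IRLS
# quadratic approximation, glmnet-style).  The objective is
#     (1/n) * negative log-likelihood + lambda * sum_j |beta_j|
# with the offset never penalized.  Continuous covariates are standardized
# to zero mean / unit variance internally so the penalty treats dose-like
# and binary covariates comparably; binary 0/1 columns are left as they
# are.  Reported coefficients are back-transformed to the original scale.
# ---------------------------------------------------------------------------


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, p = X.shape
    center = np.zeros(p)
    scale = np.ones(p)
    Xs = X.copy()
    for j in range(p):
        vals = np.unique(X[:, j])
        if np.all(np.isin(vals, [0.0, 1.0])):
            continue  # binary stays 0/1
        c = X[:, j].mean()
        s = X[:, j].std()
        if s <= 0:
            s = 1.0
        center[j] = c
        scale[j] = s
        Xs[:, j] = (X[:, j] - c) / s
    return Xs, center, scale


def _soft_threshold(v: float, t: float) -> float:
    # the tiny relative margin keeps slopes exactly zero at lambda == lambda_max,
    # where the KKT condition holds with float-rounding-order equality
    t_eff = t * (1.0 + 1e-10)
    if v > t_eff:
        return v - t
    if v < -t_eff:
        return v + t
    return 0.0


def _cd_penalized_wls(
    Xs: np.ndarray,
    w: np.ndarray,
    z: np.ndarray,
    beta: np.ndarray,
    lam: float,
    tol: float,
    max_sweeps: int = 1000,
) -> np.ndarray:
    """One penalized weighted-least-squares solve by cyclic coordinate descent.

    ``beta`` has the intercept first; only slopes are soft-thresholded.
    """
    n, p = Xs.shape
    wn = w / n
    sw = wn.sum()
    xwx = np.array([np.dot(wn * Xs[:, j], Xs[:, j]) for j in range(p)])
    resid = z - beta[0] - Xs @ beta[1:]
    for _ in range(max_sweeps):
        delta = 0.0
        # intercept
        upd = np.dot(wn, resid) / sw
        beta[0] += upd
        resid -= upd
        delta = max(delta, abs(upd))
        for j in range(p):
            if xwx[j] <= 0:
                continue
            bj = beta[j + 1]
            rho = np.dot(wn * Xs[:, j], resid) + xwx[j] * bj
            new = _soft_threshold(rho, lam) / xwx[j]
            if new != bj:
                resid -= (new - bj) * Xs[:, j]
                beta[j + 1] = new
                delta = max(delta, abs(new - bj))
        if delta < tol:
            break
    return beta


def fit_logistic_lasso(
    design: np.ndarray,
    outcomes: np.ndarray,
    lam: float,
    covariate_names: Sequence[str] | None = None,
    *,
    max_iter: int = 100,
    tol: float = 1e-10,
    warm_start: np.ndarray | None = None,
) -> FittedLogisticModel:
    """L1-penalized logistic regression at penalty strength ``lam``.

    ``warm_start`` (standardized-scale coefficients, offset first) speeds up
    path computations; the returned model carries coefficients on both the
    original (``beta``) and standardized (``beta_std``) scales.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    X, y = _check_xy(design, outcomes)
    n, p = X.shape
    if covariate_names is None:
        covariate_names = [f"x{i + 1}" for i in range(p)]

    Xs, center, scale = _standardize(X)
    if warm_start is not None:
        beta_s = np.asarray(warm_start, dtype=float).copy()
    else:
        beta_s = np.zeros(p + 1)
        prev = y.mean()
        beta_s[0] = math.log(prev / (1.0 - prev))

    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        eta = beta_s[0] + Xs @ beta_s[1:]
        mu = _sigmoid(eta)
        w = np.clip(mu * (1.0 - mu), _WEIGHT_FLOOR, None)
        z = eta + (y - mu) / w
        beta_s = _cd_penalized_wls(Xs, w, z, beta_s, lam, tol=tol * 10)
        ll = _log_likelihood(beta_s[0] + Xs @ beta_s[1:], y)
        if abs(ll - ll_old) < 1e-9 * (abs(ll) + 1e-9):
            converged = True
            break
        ll_old = ll

    # back-transform to the original covariate scale
    beta = np.empty(p + 1)
    beta[1:] = beta_s[1:] / scale
    beta[0] = beta_s[0] - np.dot(beta_s[1:], center / scale)
    ll = _log_likelihood(beta[0] + X @ beta[1:], y)

    return FittedLogisticModel(
        covariate_names=list(covariate_names),
        beta=beta,
        log_likelihood=ll,
        n_obs=n,
        n_params=p + 1,
        penalized=True,
        lam=float(lam),
        converged=converged,
        beta_std=beta_s,
    )


def _lambda_max(design: np.ndarray, outcomes: np.ndarray) -> float:
    X, y = _check_xy(design, outcomes)
    Xs, _, _ = _standardize(X)
    n = len(y)
    return float(np.max(np.abs(Xs.T @ (y - y.mean()))) / n)


def lasso_path_lambdas(
    design: np.ndarray,
    outcomes: np.ndarray,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
) -> np.ndarray:
    """Log-spaced penalty path from ``lambda_max`` (all slopes zero) down to
    ``lambda_min_ratio * lambda_max``, descending."""
    lmax = _lambda_max(design, outcomes)
    return np.geomspace(lmax, lambda_min_ratio * lmax, n_lambda)


def lasso_lambda_for_max_k(
    design: np.ndarray,
    outcomes: np.ndarray,
    k: int,
    *,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
) -> float:
    """Smallest penalty on the path that keeps at most ``k`` nonzero slopes.

    The path is walked from ``lambda_max`` downwards with warm starts; the
    walk stops at the first grid point whose active set exceeds ``k`` and the
    previous point is returned.  If the active set never exceeds ``k`` the
    path minimum is returned.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    lambdas = lasso_path_lambdas(design, outcomes, n_lambda, lambda_min_ratio)
    best = lambdas[0]
    warm = None
    for lam in lambdas:
        model = fit_logistic_lasso(design, outcomes, lam, warm_start=warm)
        warm = model.beta_std.copy()
        if model.n_nonzero_slopes() > k:
            return float(best)
        best = lam
    return float(best)


# ---------------------------------------------------------------------------
# NTCP evaluation and metrics
# ---------------------------------------------------------------------------


def ntcp(model: FittedLogisticModel, covariates: Mapping[str, float]) -> float:
    """Complication probability 1/(1+exp(-(b0 + sum bi*xi))) for one patient."""
    eta = model.beta[0]
    for name, coef in zip(model.covariate_names, model.beta[1:]):
        if name not in covariates or covariates[name] is None:
            raise KeyError(f"missing covariate '{name}' for NTCP evaluation")
        val = covariates[name]
        if isinstance(val, float) and math.isnan(val):
            raise KeyError(f"missing covariate '{name}' for NTCP evaluation")
        eta += coef * float(val)
    return float(_sigmoid(np.asarray(eta)))


def predict_proba(model: FittedLogisticModel, design: np.ndarray) -> np.ndarray:
    """Vectorized NTCP over the rows of ``design`` (columns in model order)."""
    return _sigmoid(model.linear_predictor(design))


def auc_roc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, i.e. the Mann–Whitney probability that a
    random case outscores a random control (ties count one half)."""
    labels = np.asarray(labels, dtype=float).ravel()
    scores = np.asarray(scores, dtype=float).ravel()
    if np.unique(labels).size < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, scores))


def cross_entropy(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Negative log-likelihood per sample: -(1/n) sum y ln p + (1-y) ln(1-p)."""
    p = np.asarray(probabilities, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    if p.shape != y.shape:
        raise ValueError("probabilities and labels disagree in length")
    p = np.clip(p, _PROB_CLIP, 1.0 - _PROB_CLIP)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def aic_bic(model: FittedLogisticModel) -> tuple[float, float]:
    """AIC = 2k - 2 lnL and BIC = k ln(n) - 2 lnL, k counting the offset."""
    k = model.n_params
    ll = model.log_likelihood
    return 2.0 * k - 2.0 * ll, k * math.log(model.n_obs) - 2.0 * ll


def hosmer_lemeshow(
    probabilities: np.ndarray,
    labels: np.ndarray,
    n_bins: int = 10,
) -> tuple[float, float]:
    """Hosmer–Lemeshow goodness-of-fit test over deciles of predicted risk.

    Records are sorted by predicted probability (stable sort, so boundary
    ties keep input order) and split into ``n_bins`` near-equal groups.  The
    statistic sums (O-E)^2 / (E (1 - E/m)) over groups and is referred to a
    chi-square with ``n_bins - 2`` degrees of freedom.  Groups with zero
    binomial variance are skipped with a warning and the degrees of freedom
    reduced accordingly.
    """
    p = np.asarray(probabilities, dtype=float).ravel()
    y = np.asarray(labels, dtype=float).ravel()
    n = len(p)
    if n < 2 * n_bins:
        raise ValueError(f"need at least {2 * n_bins} records for {n_bins} bins")
    order = np.argsort(p, kind="stable")
    stat = 0.0
    used = 0
    for idx in np.array_split(order, n_bins):
        m = len(idx)
        e = p[idx].sum()
        o = y[idx].sum()
        var = e * (1.0 - e / m)
        if var <= 1e-12:
            warnings.warn("Hosmer-Lemeshow bin with zero expected variance skipped")
            continue
        stat += (o - e) ** 2 / var
        used += 1
    df = used - 2
    if df < 1:
        raise ValueError("too few usable bins for the Hosmer-Lemeshow test")
    return float(stat), float(sps.chi2.sf(stat, df))


def spearman_rcc(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (Pearson correlation of mid-ranks)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("rank correlation undefined for a constant vector")
    rho = sps.spearmanr(x, y).statistic
    return float(rho)


def chi_square_test(table: np.ndarray) -> float:
    """Pearson chi-square p-value (no continuity correction) on a 2x2 table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square undefined for a zero margin")
    res = sps.chi2_contingency(t, correction=False)
    return float(res.pvalue)


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration when both groups have at most 10 observations and no
    ties across groups; otherwise the normal approximation with tie
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    exact = len(x) <= 10 and len(y) <= 10 and np.unique(pooled).size == len(pooled)
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def _fisher_rxc(table: np.ndarray) -> float:
    """Two-sided Fisher exact p on a small r x c table by complete
    enumeration of tables with the observed margins (sum of probabilities of
    tables no more probable than the observed one)."""
    t = np.asarray(table, dtype=np.int64)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    ntot = int(t.sum())
    if ntot > 400:
        raise ValueError("r x c Fisher enumeration limited to small tables")
    from math import lgamma

    def lfact(k: int) -> float:
        return lgamma(k + 1)

    const = sum(lfact(r) for r in rows) + sum(lfact(c) for c in cols) - lfact(ntot)

    def logp(cells: np.ndarray) -> float:
        return const - sum(lfact(int(c)) for c in cells.ravel())

    p_obs = logp(t)
    r, c = t.shape
    total = 0.0

    def rec(i: int, remaining_cols: np.ndarray, acc: list[np.ndarray]) -> None:
        nonlocal total
        if i == r - 1:
            last = remaining_cols
            if np.all(last >= 0):
                cand = np.vstack(acc + [last])
                lp = logp(cand)
                if lp <= p_obs + 1e-9:
                    total += math.exp(lp)
            return
        # enumerate row i with sum rows[i] within remaining column capacity
        def fill(j: int, left: int, row: list[int]) -> None:
            if j == c - 1:
                if 0 <= left <= remaining_cols[j]:
                    rec(i + 1, remaining_cols - np.array(row + [left]), acc + [np.array(row + [left])])
                return
            for v in range(min(left, int(remaining_cols[j])) + 1):
                fill(j + 1, left - v, row + [v])

        fill(0, int(rows[i]), [])

    rec(0, cols.copy(), [])
    return float(min(total, 1.0))


def fisher_exact_test(table: np.ndarray) -> float:
    """Two-sided Fisher exact test; 2x2 tables use the hypergeometric form,
    larger (small-count) tables fall back to complete enumeration."""
    t = np.asarray(table, dtype=np.int64)
    if t.shape == (2, 2):
        return float(sps.fisher_exact(t, alternative="two-sided")[1])
    return _fisher_rxc(t)
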