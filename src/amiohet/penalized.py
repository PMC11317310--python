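"""Weighted lasso-penalized logistic regression with CV penalty selection.

This is the shared estimation engine for both model-fitting stages of the
benefit-scoring pipeline: the treatment-assignment (propensity) model and
the modified-covariate benefit model. The objective is

    (1/n) * sum_i w_i * log(1 + exp(-(2 y_i - 1) * eta_i))
        + lambda * sum_j pf_j * |beta_j|

with observation weights ``w`` (internally normalized to mean 1, so a
lambda has the same meaning regardless of the weight scale), per-feature
penalty factors ``pf`` (internally rescaled to sum to the number of
features, matching the convention of mainstream lasso software), and
optional internal standardization of the design with coefficients
returned on the original scale.

Setting ``fit_intercept=False`` and putting an unpenalized signed
constant column in ``X`` yields the modified-covariate parametrization
eta_i = (2 T_i - 1) * (b0 + beta' x_i) used by the benefit model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._solver import binomial_deviance, cd_logistic_path, newton_logistic
from .exceptions import ConfigurationError, DegenerateOutcomeError

__all__ = ["LassoLogisticPath", "CVLassoFit", "lasso_logistic_path", "cv_lasso_logistic"]

_DEFAULT_N_LAMBDA = 60
_TOL = 1e-7
_MAX_IRLS = 30
_MAX_CD = 200


@dataclass
class LassoLogisticPath:
    """Solution path of the penalized fit, on the original data scale."""

    lambdas: np.ndarray
    intercepts: np.ndarray          # (L,) zeros when fit_intercept=False
    coefs: np.ndarray               # (L, p)
    fit_intercept: bool

    def predict_eta(self, X: np.ndarray, index: int) -> np.ndarray:
        return self.intercepts[index] + X @ self.coefs[index]


@dataclass
class CVLassoFit:
    """CV-selected penalized fit."""

    intercept: float
    coef: np.ndarray
    lambda_: float
    lambda_index: int
    lambdas: np.ndarray
    cv_deviance: np.ndarray
    cv_deviance_se: np.ndarray
    lambda_rule: str
    n_folds: int
    seed: int | None
    path: LassoLogisticPath = field(repr=False)

    def predict_eta(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + X @ self.coef

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = self.predict_eta(X)
        return 1.0 / (1.0 + np.exp(-eta))


def _prepare(X, y, sample_weight, penalty_factor):
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ConfigurationError(f"y has length {y.shape[0]}, X has {n} rows")
    if not np.all((y == 0) | (y == 1)):
        raise ConfigurationError("y must be binary 0/1")
    if y.min() == y.max():
        raise DegenerateOutcomeError("outcome is constant; logistic fit is degenerate")
    if sample_weight is None:
        w = np.ones(n)
    else:
        w = np.asarray(sample_weight, dtype=np.float64).ravel()
        if w.shape[0] != n or np.any(w < 0) or w.sum() <= 0:
            raise ConfigurationError("sample_weight must be nonnegative with positive sum")
    w = w / w.mean()
    if penalty_factor is None:
        pf = np.ones(p)
    else:
        pf = np.asarray(penalty_factor, dtype=np.float64).ravel()
        if pf.shape[0] != p or np.any(pf < 0):
            raise ConfigurationError("penalty_factor must be nonnegative, one per column")
        if pf.sum() == 0:
            raise ConfigurationError("at least one column must be penalized")
    pf = pf * (p / pf.sum())
    return X, y, w, pf


def _standardize(X, w, fit_intercept, standardize):
    """glmnet-style weighted scaling; centering only with an intercept."""
    n, p = X.shape
    means = np.zeros(p)
    scales = np.ones(p)
    if not standardize:
        return X, means, scales
    wm = w / w.sum()
    mu = wm @ X
    var = wm @ (X - mu) ** 2
    scales = np.sqrt(var)
    scales[scales < 1e-12] = 1.0
    if fit_intercept:
        means = mu
        Xs = (X - means) / scales
    else:
        Xs = X / scales
    return np.ascontiguousarray(Xs), means, scales


def _lambda_max(Xs, y, w, pf, fit_intercept):
    """Smallest lambda at which all penalized coefficients are zero.

    Needs the null model (intercept and unpenalized columns only) first:
    a closed form for the intercept-only case, otherwise a small Newton
    fit restricted to the unpenalized columns.
    """
    n = Xs.shape[0]
    free = np.flatnonzero(pf == 0)
    eta = np.zeros(n)
    if fit_intercept:
        mu = min(max(np.average(y, weights=w), 1e-10), 1 - 1e-10)
        eta += np.log(mu / (1 - mu))
    if free.size:
        cols = Xs[:, free]
        if fit_intercept:
            cols = np.column_stack([np.ones(n), cols])
        beta, *_ = newton_logistic(np.ascontiguousarray(cols), y, w, 50, 1e-10)
        eta = cols @ beta
    pvec = 1.0 / (1.0 + np.exp(-eta))
    grad = np.abs(Xs.T @ (w * (y - pvec))) / n
    pen = pf > 0
    lam = np.max(grad[pen] / pf[pen])
    return max(lam, 1e-10)


def lasso_logistic_path(
    X,
    y,
    sample_weight=None,
    penalty_factor=None,
    lambdas=None,
    n_lambda: int = _DEFAULT_N_LAMBDA,
    lambda_min_ratio: float | None = None,
    fit_intercept: bool = True,
    standardize: bool = True,
    tol: float = _TOL,
) -> LassoLogisticPath:
    """Fit the full regularization path.

    When ``lambdas`` is not given, a log-spaced path from lambda_max down
    to ``lambda_min_ratio * lambda_max`` is built (ratio defaults to 1e-4
    when n > p, 1e-2 otherwise, as in glmnet).
    """
    X, y, w, pf = _prepare(X, y, sample_weight, penalty_factor)
    n, p = X.shape
    Xs, means, scales = _standardize(X, w, fit_intercept, standardize)

    if lambdas is None:
        lam_max = _lambda_max(Xs, y, w, pf, fit_intercept)
        if lambda_min_ratio is None:
            lambda_min_ratio = 1e-4 if n > p else 1e-2
        lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)
    else:
        lambdas = np.asarray(lambdas, dtype=np.float64).ravel()
        if np.any(np.diff(lambdas) > 0):
            lambdas = np.sort(lambdas)[::-1].copy()

    b0s, betas = cd_logistic_path(Xs, y, w, pf, lambdas, fit_intercept, tol, _MAX_IRLS, _MAX_CD)
    coefs = betas / scales[None, :]
    if fit_intercept:
        icepts = b0s - coefs @ means
    else:
        icepts = np.zeros_like(b0s)
    return LassoLogisticPath(lambdas=lambdas, intercepts=icepts, coefs=coefs,
                             fit_intercept=fit_intercept)


def _fold_assignments(n: int, n_folds: int, seed: int | None) -> np.ndarray:
    rng = np.random.default_rng(seed)
    folds = np.resize(np.arange(n_folds), n)
    rng.shuffle(folds)
    return folds


def cv_lasso_logistic(
    X,
    y,
    sample_weight=None,
    penalty_factor=None,
    n_folds: int = 10,
    seed: int | None = None,
    lambda_rule: str = "min",
    lambdas=None,
    n_lambda: int = _DEFAULT_N_LAMBDA,
    lambda_min_ratio: float | None = None,
    fit_intercept: bool = True,
    standardize: bool = True,
    tol: float = _TOL,
) -> CVLassoFit:
    """K-fold CV over the lambda path, minimizing weighted binomial deviance.

    ``lambda_rule`` is ``"min"`` (deviance-minimizing lambda) or ``"1se"``
    (largest lambda within one standard error of the minimum). Weights are
    held fixed across folds; held-out deviance is weighted by the held-out
    observations' weights.
    """
    if lambda_rule not in ("min", "1se"):
        raise ConfigurationError(f"unknown lambda_rule {lambda_rule!r}")
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if n_folds < 2 or n_folds > n:
        raise ConfigurationError(f"n_folds={n_folds} invalid for n={n}")

    full = lasso_logistic_path(
        X, y, sample_weight, penalty_factor, lambdas=lambdas, n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio, fit_intercept=fit_intercept,
        standardize=standardize, tol=tol,
    )
    lambdas_path = full.lambdas
    yv = np.asarray(y, dtype=np.float64).ravel()
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=np.float64)

    folds = _fold_assignments(n, n_folds, seed)
    L = lambdas_path.shape[0]
    fold_dev = np.full((n_folds, L), np.nan)
    fold_wsum = np.zeros(n_folds)
    for k in range(n_folds):
        test = folds == k
        train = ~test
        if yv[train].min() == yv[train].max():
            # degenerate training fold: skip (deviance averaged over the rest)
            continue
        sub = lasso_logistic_path(
            X[train], yv[train], w[train],
            penalty_factor, lambdas=lambdas_path, fit_intercept=fit_intercept,
            standardize=standardize, tol=tol,
        )
        Xt = np.ascontiguousarray(X[test])
        for l in range(L):
            eta = sub.predict_eta(Xt, l)
            fold_dev[k, l] = binomial_deviance(yv[test], eta, w[test])
        fold_wsum[k] = w[test].sum()

    ok = fold_wsum > 0
    ws = fold_wsum[ok] / fold_wsum[ok].sum()
    cvm = ws @ fold_dev[ok]
    k_ok = int(ok.sum())
    cvsd = np.sqrt(np.nansum(((fold_dev[ok] - cvm) ** 2) * ws[:, None], axis=0) / max(k_ok - 1, 1))

    i_min = int(np.argmin(cvm))
    if lambda_rule == "min":
        idx = i_min
    else:
        thresh = cvm[i_min] + cvsd[i_min]
        idx = int(np.argmax(cvm <= thresh))  # first (largest-lambda) index within 1 SE

    return CVLassoFit(
        intercept=float(full.intercepts[idx]),
        coef=full.coefs[idx].copy(),
        lambda_=float(lambdas_path[idx]),
        lambda_index=idx,
        lambdas=lambdas_path,
        cv_deviance=cvm,
        cv_deviance_se=cvsd,
        lambda_rule=lambda_rule,
        n_folds=n_folds,
        seed=seed,
        path=full,
    )
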