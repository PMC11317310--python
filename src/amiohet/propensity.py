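"""Treatment-assignment model and inverse-probability weights.

The propensity score e(x) = P(T=1 | x) is estimated by lasso-penalized
logistic regression with the penalty chosen by K-fold cross-validation;
balancing weights are the inverse probability of the *received*
treatment, w_i = 1 / (T_i e_i + (1 - T_i)(1 - e_i)), after clamping the
fitted probabilities away from 0 and 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError, EstimationError
from .penalized import cv_lasso_logistic

__all__ = ["PropensityFit", "fit_propensity", "compute_weights"]


@dataclass
class PropensityFit:
    intercept: float
    coef: np.ndarray
    lambda_: float
    e_hat: np.ndarray           # truncated to [eps, 1 - eps]
    truncation: float
    cv_folds: int
    lambda_rule: str
    seed: int | None

    @property
    def coefficients(self) -> np.ndarray:
        """Intercept-first coefficient vector on the original covariate scale."""
        return np.concatenate([[self.intercept], self.coef])


def fit_propensity(
    X,
    T,
    cv_folds: int = 10,
    seed: int | None = None,
    lambda_rule: str = "min",
    truncation: float = 0.01,
    n_lambda: int = 60,
    lambda_min_ratio: float | None = None,
) -> PropensityFit:
    """CV-lasso logistic fit of treatment on the encoded covariates."""
    T = np.asarray(T, dtype=np.int64).ravel()
    if T.min() == T.max():
        raise EstimationError("both treatment arms must be present to fit a propensity model")
    _check_truncation(truncation)
    fit = cv_lasso_logistic(
        np.asarray(X, dtype=float), T, n_folds=cv_folds, seed=seed,
        lambda_rule=lambda_rule, n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio, fit_intercept=True,
        standardize=True,
    )
    e = fit.predict_proba(np.asarray(X, dtype=float))
    e = np.clip(e, truncation, 1.0 - truncation)
    return PropensityFit(
        intercept=fit.intercept, coef=fit.coef, lambda_=fit.lambda_,
        e_hat=e, truncation=truncation, cv_folds=cv_folds,
        lambda_rule=lambda_rule, seed=seed,
    )


def _check_truncation(eps: float) -> None:
    if not (0.0 <= eps < 0.5):
        raise ConfigurationError(f"truncation must lie in [0, 0.5), got {eps}")


def compute_weights(e_hat, T, truncation: float = 0.01) -> np.ndarray:
    """Inverse probability of received treatment, w >= 1.

    ``e_hat`` may be a :class:`PropensityFit` (its stored probabilities
    are used) or a raw probability vector, which is clamped to
    ``[truncation, 1 - truncation]`` first.
    """
    _check_truncation(truncation)
    if isinstance(e_hat, PropensityFit):
        e = e_hat.e_hat
    else:
        e = np.clip(np.asarray(e_hat, dtype=float), truncation, 1.0 - truncation)
    T = np.asarray(T, dtype=float).ravel()
    if e.shape[0] != T.shape[0]:
        raise ConfigurationError("propensity and treatment vectors differ in length")
    return 1.0 / (T * e + (1.0 - T) * (1.0 - e))
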