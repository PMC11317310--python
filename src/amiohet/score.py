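"""Linear personalized benefit score via the modified-covariate method.

The score s(x) = b0 + beta' x is fit by minimizing the propensity-
weighted, lasso-penalized logistic likelihood in which every working
covariate (including the intercept column) is multiplied by (2T - 1):

    (1/n) sum_i w_i log(1 + exp(-(2 y_i - 1)(2 T_i - 1)(b0 + beta' x_i)))
        + lambda ||beta||_1

The intercept is unpenalized. Because the treatment contrast enters the
outcome model as (2T - 1) s(x) / 2, a positive score means the patient is
expected to do better under treatment: patients with s(x) >= 0 form the
"benefit" subgroup, the rest the "no-benefit" subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .penalized import cv_lasso_logistic

__all__ = [
    "BenefitModel", "ScoreAssignment", "build_modified_design",
    "fit_benefit_model", "score_patients", "assign_subgroup",
]

SUBGROUP_BENEFIT = "benefit"
SUBGROUP_NO_BENEFIT = "no_benefit"


@dataclass
class BenefitModel:
    intercept: float            # b0 of the scoring equation
    coef: np.ndarray            # beta on the original covariate scale
    lambda_: float
    outcome: str                # "neuro" or "survival"
    cv_folds: int
    lambda_rule: str
    seed: int | None
    feature_names: list | None = None

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coef": list(map(float, self.coef)),
            "lambda": self.lambda_,
            "outcome": self.outcome,
            "feature_names": self.feature_names,
        }


@dataclass
class ScoreAssignment:
    score: np.ndarray
    subgroup: np.ndarray        # array of "benefit" / "no_benefit"
    provenance: str             # "in_sample" or "cross_validated"

    @property
    def benefit_mask(self) -> np.ndarray:
        return self.subgroup == SUBGROUP_BENEFIT

    @property
    def single_subgroup(self) -> bool:
        """Degenerate partition: every patient fell on one side of the cutoff."""
        return bool(self.benefit_mask.all() or (~self.benefit_mask).all())


def build_modified_design(X, T) -> np.ndarray:
    """Working design [(2T-1), (2T-1) * X]: column 0 is the signed intercept."""
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float).ravel()
    if not np.all((T == 0) | (T == 1)):
        raise ValidationError("treatment must be coded 0/1")
    s = 2.0 * T - 1.0
    return np.column_stack([s, X * s[:, None]])


def fit_benefit_model(
    X,
    T,
    y,
    weights,
    cv_folds: int = 10,
    seed: int | None = None,
    lambda_rule: str = "min",
    outcome: str = "neuro",
    n_lambda: int = 60,
    lambda_min_ratio: float | None = None,
    feature_names=None,
) -> BenefitModel:
    """Fit the weighted modified-covariate lasso and return the scoring model.

    ``weights`` are the propensity-based balancing weights, held fixed
    during the penalty cross-validation (folds re-use the supplied
    weights rather than re-estimating the propensity model).
    """
    Xa = np.asarray(X, dtype=float)
    # center covariates (weighted) before signing: an exact
    # reparametrization — the shift is absorbed by the unpenalized signed
    # intercept — that removes the near-collinearity between the signed
    # intercept and signed raw-scale columns, and makes the internal
    # standardization scale each column by the covariate's own sd
    wv = np.ones(Xa.shape[0]) if weights is None else np.asarray(weights, dtype=float)
    mu = (wv / wv.sum()) @ Xa
    M = build_modified_design(Xa - mu, T)
    pf = np.ones(M.shape[1])
    pf[0] = 0.0                   # signed intercept column is unpenalized
    fit = cv_lasso_logistic(
        M, y, sample_weight=weights, penalty_factor=pf, n_folds=cv_folds,
        seed=seed, lambda_rule=lambda_rule, n_lambda=n_lambda,
        lambda_min_ratio=lambda_min_ratio, fit_intercept=False, standardize=True,
    )
    if feature_names is None and hasattr(X, "columns"):
        feature_names = list(X.columns)
    beta = fit.coef[1:].copy()
    return BenefitModel(
        intercept=float(fit.coef[0] - beta @ mu), coef=beta,
        lambda_=fit.lambda_, outcome=outcome, cv_folds=cv_folds,
        lambda_rule=lambda_rule, seed=seed, feature_names=feature_names,
    )


def score_patients(model: BenefitModel, X) -> np.ndarray:
    """s_i = b0 + beta' x_i for each row of X (model's encoding assumed)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.coef.shape[0]:
        raise ValidationError(
            f"design has {X.shape[1] if X.ndim == 2 else 'wrong'} columns, "
            f"model expects {model.coef.shape[0]}")
    return model.intercept + X @ model.coef


def assign_subgroup(scores, cutoff: float = 0.0,
                    provenance: str = "in_sample") -> ScoreAssignment:
    """Dichotomize scores at the cutoff: score >= cutoff -> benefit."""
    scores = np.asarray(scores, dtype=float).ravel()
    if not np.all(np.isfinite(scores)):
        raise ValidationError("scores must be finite")
    labels = np.where(scores >= cutoff, SUBGROUP_BENEFIT, SUBGROUP_NO_BENEFIT)
    return ScoreAssignment(score=scores, subgroup=labels, provenance=provenance)
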