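"""Nested cross-validation: leakage-free per-patient scores and subgroups.

The outer loop partitions patients into treatment-stratified folds; for
each outer fold the propensity model, the balancing weights and the
benefit model are all fit on the training portion only (with their
penalties tuned by the inner CV loop), and the held-out patients are
scored with that model. Concatenating over outer folds gives every
patient a score from a model that never saw their outcome or treatment,
which is the internal-validation contract the subgroup inference relies
on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .cohort import AnalysisCohort
from .config import PipelineConfig, child_seed
from .exceptions import ConfigurationError, EstimationError
from .propensity import compute_weights, fit_propensity
from .score import ScoreAssignment, assign_subgroup, fit_benefit_model, score_patients

__all__ = ["CVPlan", "make_cv_plan", "cross_validated_scores"]


@dataclass
class CVPlan:
    n: int
    outer_k: int
    inner_k: int
    seed: int
    fold: np.ndarray            # outer test-fold index per patient
    stratify_by: str = "treatment"

    def test_indices(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.fold == k)


def make_cv_plan(n: int, outer_k: int = 5, inner_k: int = 10,
                 seed: int = 0, stratify: np.ndarray | None = None) -> CVPlan:
    """Reproducible stratified outer partition (by treatment arm by default)."""
    if outer_k < 2 or outer_k > n:
        raise ConfigurationError(f"outer_k={outer_k} invalid for n={n}")
    if inner_k < 2:
        raise ConfigurationError("inner_k must be >= 2")
    fold = np.empty(n, dtype=np.int64)
    if stratify is None:
        stratify = np.zeros(n, dtype=int)
    splitter = StratifiedKFold(n_splits=outer_k, shuffle=True, random_state=seed % (2**32))
    for k, (_, test) in enumerate(splitter.split(np.zeros(n), np.asarray(stratify))):
        fold[test] = k
    return CVPlan(n=n, outer_k=outer_k, inner_k=inner_k, seed=seed, fold=fold)


def cross_validated_scores(cohort: AnalysisCohort, plan: CVPlan,
                           config: PipelineConfig, outcome: str | None = None) -> ScoreAssignment:
    """Nested-CV scores and subgroup labels for every patient.

    Per outer fold: fit propensity (inner-CV lambda) on the training
    portion, derive weights there, fit the benefit model (inner-CV
    lambda, weighted), then score the held-out fold. Returns an
    assignment with ``provenance="cross_validated"``.
    """
    outcome = outcome or config.benefit.outcome
    X = cohort.X.to_numpy(dtype=float)
    T = cohort.T
    y = cohort.outcome(outcome)
    if plan.n != cohort.n:
        raise ConfigurationError("CV plan size does not match cohort size")

    scores = np.empty(cohort.n)
    for k in range(plan.outer_k):
        test = plan.fold == k
        train = ~test
        T_tr = T[train]
        if T_tr.min() == T_tr.max():
            raise EstimationError(f"outer training set for fold {k} has a single treatment arm")
        pfit = fit_propensity(
            X[train], T_tr, cv_folds=plan.inner_k,
            seed=child_seed(config.seed, "nested_propensity", plan.seed, k),
            lambda_rule=config.propensity.lambda_rule,
            truncation=config.propensity.truncation,
            n_lambda=config.propensity.n_lambda,
            lambda_min_ratio=config.propensity.lambda_min_ratio,
        )
        w = compute_weights(pfit, T_tr, config.propensity.truncation)
        bmodel = fit_benefit_model(
            X[train], T_tr, y[train], w, cv_folds=plan.inner_k,
            seed=child_seed(config.seed, "nested_benefit", plan.seed, k),
            lambda_rule=config.benefit.lambda_rule, outcome=outcome,
            n_lambda=config.benefit.n_lambda,
            lambda_min_ratio=config.benefit.lambda_min_ratio,
        )
        scores[test] = score_patients(bmodel, X[test])

    assignment = assign_subgroup(scores, cutoff=0.0, provenance="cross_validated")
    return assignment
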