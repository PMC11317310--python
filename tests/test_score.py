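"""Benefit-score fitting, scoring, and subgroup assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from amiohet import (assign_subgroup, build_modified_design, compute_weights,
                     fit_benefit_model, fit_propensity, score_patients)
from amiohet.exceptions import DegenerateOutcomeError, ValidationError
from amiohet.score import BenefitModel


class TestModifiedDesign:
    def test_signs_follow_treatment(self):
        X = np.arange(6.0).reshape(3, 2)
        T = np.array([1, 0, 1])
        M = build_modified_design(X, T)
        np.testing.assert_array_equal(M[:, 0], [1, -1, 1])
        np.testing.assert_array_equal(M[0, 1:], X[0])
        np.testing.assert_array_equal(M[1, 1:], -X[1])

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 4))
        T = rng.integers(0, 2, 50)
        M = build_modified_design(X, T)
        for i in range(50):
            s = 2 * T[i] - 1
            assert M[i, 0] == s
            np.testing.assert_allclose(M[i, 1:], s * X[i])

    def test_permuting_treatment_flips_exactly_changed_rows(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 3))
        T = rng.integers(0, 2, 40)
        Tp = rng.permutation(T)
        M, Mp = build_modified_design(X, T), build_modified_design(X, Tp)
        changed = T != Tp
        np.testing.assert_allclose(Mp[changed], -M[changed])
        np.testing.assert_allclose(Mp[~changed], M[~changed])

    def test_non_binary_treatment_rejected(self):
        with pytest.raises(ValidationError):
            build_modified_design(np.zeros((3, 2)), np.array([0, 1, 2]))


class TestFitBenefitModel:
    def _loss(self, par, X, T, y, w):
        s = 2 * T - 1.0
        eta = s * (par[0] + X @ par[1:])
        wn = w / np.mean(w)
        return np.sum(wn * np.logaddexp(0.0, -(2 * y - 1) * eta)) / len(y)

    def test_lambda_zero_matches_independent_optimizer(self):
        """Unpenalized modified-covariate fit equals direct weighted MLE of
        the identical loss from an independent optimizer (n=40)."""
        rng = np.random.default_rng(3)
        n, p = 40, 2
        X = np.column_stack([rng.normal(60, 15, n), rng.integers(0, 2, n)]).astype(float)
        T = rng.integers(0, 2, n)
        y = (rng.random(n) < 0.4).astype(float)
        w = rng.uniform(1.0, 3.0, n)
        ref = minimize(self._loss, np.zeros(p + 1), args=(X, T, y, w),
                       method="BFGS", options={"gtol": 1e-12}).x
        # lambda path forced to 0 via a two-point path ending at zero
        from amiohet.penalized import lasso_logistic_path
        mu = (w / w.sum()) @ X
        M = build_modified_design(X - mu, T)
        pf = np.r_[0.0, np.ones(p)]
        path = lasso_logistic_path(M, y, w, penalty_factor=pf, lambdas=[0.0],
                                   fit_intercept=False, tol=1e-10)
        b = path.coefs[0]
        fitted = np.r_[b[0] - b[1:] @ mu, b[1:]]
        assert np.max(np.abs(fitted - ref)) < 1e-5

    def test_saturated_penalty_gives_constant_score(self):
        rng = np.random.default_rng(4)
        n = 200
        X = rng.normal(size=(n, 3))
        T = rng.integers(0, 2, n)
        y = (rng.random(n) < 0.3).astype(float)
        model = fit_benefit_model(X, T, y, np.ones(n), cv_folds=3, seed=0,
                                  lambda_rule="1se", n_lambda=5, lambda_min_ratio=0.9)
        scores = score_patients(model, X)
        if np.all(model.coef == 0):
            assert np.ptp(scores) == 0.0

    def test_anti_symmetry_under_treatment_flip(self):
        """Relabeling T -> 1-T (weights recomputed) negates the score."""
        rng = np.random.default_rng(5)
        n = 400
        X = rng.normal(size=(n, 4))
        T = rng.integers(0, 2, n)
        y = (rng.random(n) < 0.35).astype(float)
        e = np.full(n, 0.5)
        w = compute_weights(e, T)
        w_flip = compute_weights(e, 1 - T)
        m1 = fit_benefit_model(X, T, y, w, cv_folds=4, seed=9)
        m2 = fit_benefit_model(X, 1 - T, y, w_flip, cv_folds=4, seed=9)
        s1 = score_patients(m1, X)
        s2 = score_patients(m2, X)
        np.testing.assert_allclose(s1, -s2, atol=5e-4)

    def test_degenerate_outcome_rejected(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        T = np.resize([0, 1], 20)
        with pytest.raises(DegenerateOutcomeError):
            fit_benefit_model(X, T, np.zeros(20), np.ones(20), cv_folds=2)

    def test_null_structure_gives_effectively_constant_score(self):
        """With no planted heterogeneity the CV-selected score carries no
        meaningful covariate signal (sd-scaled coefficients < 0.02) in at
        least 80% of replicates."""
        from amiohet import apply_exclusions, default_config, generate_cohort
        flat = 0
        n_rep = 5
        for seed in range(n_rep):
            raw, _ = generate_cohort(default_config(
                n_patients=10000, seed=seed, benefit_coefs=np.zeros(11)))
            cohort, _ = apply_exclusions(raw)
            X = cohort.X.to_numpy(float)
            pfit = fit_propensity(X, cohort.T, cv_folds=10, seed=seed + 1)
            w = compute_weights(pfit, cohort.T)
            model = fit_benefit_model(cohort.X, cohort.T, cohort.y_neuro, w,
                                      cv_folds=10, seed=seed + 2)
            spread = np.max(np.abs(model.coef) * X.std(axis=0))
            flat += spread < 0.02
        assert flat >= 0.8 * n_rep

    def test_sign_recovery_on_planted_structure(self, large_cohort_20k):
        """Fitted coefficient signs match the planted interaction signs."""
        cohort, _ = large_cohort_20k
        X = cohort.X.to_numpy(float)
        pfit = fit_propensity(X, cohort.T, cv_folds=5, seed=1)
        w = compute_weights(pfit, cohort.T)
        model = fit_benefit_model(cohort.X, cohort.T, cohort.y_neuro, w,
                                  cv_folds=5, seed=2)
        coef = dict(zip(model.feature_names, model.coef))
        assert coef["age"] > 0
        assert coef["call_to_arrival_min"] > 0
        assert coef["witness"] < 0
        assert coef["defib_1or2"] < 0
        assert coef["defib_3plus"] < 0
        assert coef["hypothermia"] > 0
        assert coef["prehosp_epi"] > 0


class TestScoringAndAssignment:
    def test_constant_model_scores(self):
        model = BenefitModel(intercept=0.3, coef=np.zeros(3), lambda_=1.0,
                             outcome="neuro", cv_folds=5, lambda_rule="min", seed=0)
        s = score_patients(model, np.random.default_rng(0).normal(size=(7, 3)))
        np.testing.assert_allclose(s, 0.3)

    def test_one_hot_single_coefficient(self):
        model = BenefitModel(intercept=0.0, coef=np.array([1.2, 0.0]), lambda_=0.1,
                             outcome="neuro", cv_folds=5, lambda_rule="min", seed=0)
        assert score_patients(model, np.array([[1.0, 0.0]]))[0] == pytest.approx(1.2)

    def test_matches_naive_dot_product(self):
        rng = np.random.default_rng(8)
        beta = rng.normal(size=5)
        X = rng.normal(size=(30, 5))
        model = BenefitModel(intercept=0.7, coef=beta, lambda_=0.0,
                             outcome="neuro", cv_folds=5, lambda_rule="min", seed=0)
        s = score_patients(model, X)
        naive = np.array([0.7 + sum(beta[j] * X[i, j] for j in range(5)) for i in range(30)])
        np.testing.assert_allclose(s, naive, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        model = BenefitModel(intercept=0.0, coef=np.zeros(3), lambda_=0.0,
                             outcome="neuro", cv_folds=5, lambda_rule="min", seed=0)
        with pytest.raises(ValidationError):
            score_patients(model, np.zeros((5, 4)))

    def test_zero_score_is_benefit(self):
        a = assign_subgroup(np.array([0.0, -1e-9, 1e-9]))
        assert a.subgroup.tolist() == ["benefit", "no_benefit", "benefit"]

    def test_single_subgroup_flagged(self):
        a = assign_subgroup(np.array([0.2, 0.5, 1.0]))
        assert a.single_subgroup
        b = assign_subgroup(np.array([-0.2, 0.5]))
        assert not b.single_subgroup

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValidationError):
            assign_subgroup(np.array([0.1, np.nan]))
        with pytest.raises(ValidationError):
            assign_subgroup(np.array([np.inf]))

    @given(st.lists(st.floats(-5, 5), min_size=1, max_size=50),
           st.floats(-1, 1))
    @settings(max_examples=80, deadline=None)
    def test_cutoff_partition_property(self, scores, cutoff):
        a = assign_subgroup(np.array(scores), cutoff=cutoff)
        mask = a.benefit_mask
        np.testing.assert_array_equal(mask, np.array(scores) >= cutoff)
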