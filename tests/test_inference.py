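"""Interaction model, bootstrap CI, permutation test, outcome tables."""

import numpy as np
import pandas as pd
import pytest

from amiohet import (bootstrap_ci, fit_interaction_model, permutation_test,
                     subgroup_outcome_table)
from amiohet.cohort import AnalysisCohort, COVARIATE_COLUMNS
from amiohet.config import BenefitConfig, CVConfig, InferenceConfig, PipelineConfig, \
    PropensityConfig
from amiohet.exceptions import ConfigurationError, EstimationError
from amiohet.inference import perm_pvalue


def _cell_cohort(n_per_cell, probs, seed=0):
    """Cohort whose outcome depends only on (T, S) with given cell
    probabilities probs[(t, s)]; covariates are pure noise."""
    rng = np.random.default_rng(seed)
    rows = []
    for t in (0, 1):
        for s in (0, 1):
            for _ in range(n_per_cell):
                rows.append((t, s))
    T = np.array([r[0] for r in rows])
    S = np.array([r[1] for r in rows])
    n = len(T)
    y = np.array([rng.random() < probs[(t, s)] for t, s in rows]).astype(np.int64)
    X = pd.DataFrame(rng.normal(size=(n, len(COVARIATE_COLUMNS))),
                     columns=COVARIATE_COLUMNS)
    co = pd.DataFrame({"ecpr": rng.integers(0, 2, n),
                       "pci": rng.integers(0, 2, n),
                       "mth": rng.integers(0, 2, n)})
    frame = X.copy()
    frame["amiodarone"] = T
    cohort = AnalysisCohort(
        patient_id=np.arange(n), X=X, T=T, y_neuro=y, y_surv=y,
        cointerventions=co, frame=frame,
    )
    return cohort, S


class TestInteractionModel:
    def test_interaction_log_or_matches_cell_cross_ratio(self):
        """Closed-form oracle: with the outcome depending only on T and S,
        the interaction log-OR equals the empirical-cell cross-ratio."""
        probs = {(0, 0): 0.30, (0, 1): 0.10, (1, 0): 0.25, (1, 1): 0.22}
        cohort, S = _cell_cohort(2500, probs, seed=1)
        fit = fit_interaction_model(cohort, S.astype(float), outcome="neuro")

        def logit(p):
            return np.log(p / (1 - p))
        y = cohort.y_neuro
        emp = {}
        for t in (0, 1):
            for s in (0, 1):
                mask = (cohort.T == t) & (S == s)
                emp[(t, s)] = y[mask].mean()
        expected = (logit(emp[1, 1]) - logit(emp[1, 0])) - (logit(emp[0, 1]) - logit(emp[0, 0]))
        # covariates are noise, so the adjusted estimate approximates the
        # saturated-cell value; equality is exact only in expectation
        assert fit.interaction_log_or == pytest.approx(expected, abs=0.08)

    def test_null_simulation_ors_near_one(self):
        probs = {(t, s): 0.5 for t in (0, 1) for s in (0, 1)}
        cohort, S = _cell_cohort(2500, probs, seed=2)
        fit = fit_interaction_model(cohort, S.astype(float))
        named = fit.table.set_index("term")
        for term in ("amiodarone", "subgroup", "amiodarone_x_subgroup"):
            assert 0.9 < named.loc[term, "or_"] < 1.1

    def test_row_duplication_leaves_point_estimates_unchanged(self):
        probs = {(0, 0): 0.3, (0, 1): 0.15, (1, 0): 0.2, (1, 1): 0.35}
        cohort, S = _cell_cohort(150, probs, seed=3)
        fit1 = fit_interaction_model(cohort, S.astype(float))
        idx = np.r_[np.arange(cohort.n), np.arange(cohort.n)]
        doubled = AnalysisCohort(
            patient_id=np.arange(2 * cohort.n), X=cohort.X.iloc[idx].reset_index(drop=True),
            T=cohort.T[idx], y_neuro=cohort.y_neuro[idx], y_surv=cohort.y_surv[idx],
            cointerventions=cohort.cointerventions.iloc[idx].reset_index(drop=True),
            frame=cohort.frame.iloc[idx].reset_index(drop=True),
        )
        fit2 = fit_interaction_model(doubled, S[idx].astype(float))
        np.testing.assert_allclose(fit2.table.coef.to_numpy(),
                                   fit1.table.coef.to_numpy(), atol=1e-6)

    def test_matches_statsmodels(self):
        """Independent cross-check of the Newton MLE and Wald intervals."""
        sm = pytest.importorskip("statsmodels.api")
        probs = {(0, 0): 0.3, (0, 1): 0.15, (1, 0): 0.2, (1, 1): 0.35}
        cohort, S = _cell_cohort(400, probs, seed=4)
        fit = fit_interaction_model(cohort, S.astype(float))
        from amiohet.inference import _interaction_design
        D = _interaction_design(cohort, S.astype(float))
        ref = sm.GLM(cohort.y_neuro, D, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.table.coef.to_numpy(), ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.table.se.to_numpy(), ref.bse, rtol=1e-4)

    def test_empty_subgroup_rejected(self):
        probs = {(t, s): 0.4 for t in (0, 1) for s in (0, 1)}
        cohort, S = _cell_cohort(50, probs, seed=5)
        with pytest.raises(EstimationError):
            fit_interaction_model(cohort, np.ones(cohort.n))


class TestBootstrap:
    def test_same_seed_same_ci(self):
        probs = {(0, 0): 0.3, (0, 1): 0.15, (1, 0): 0.2, (1, 1): 0.35}
        cohort, S = _cell_cohort(300, probs, seed=6)
        ci1 = bootstrap_ci(cohort, S.astype(float), B=200, seed=12)
        ci2 = bootstrap_ci(cohort, S.astype(float), B=200, seed=12)
        assert (ci1.or_low, ci1.or_high) == (ci2.or_low, ci2.or_high)

    def test_ci_brackets_point_estimate(self):
        probs = {(0, 0): 0.3, (0, 1): 0.15, (1, 0): 0.2, (1, 1): 0.35}
        cohort, S = _cell_cohort(300, probs, seed=7)
        fit = fit_interaction_model(cohort, S.astype(float))
        ci = bootstrap_ci(cohort, S.astype(float), B=400, seed=1)
        assert ci.or_low <= fit.interaction_or <= ci.or_high

    def test_strong_interaction_ci_excludes_one(self):
        probs = {(0, 0): 0.30, (0, 1): 0.10, (1, 0): 0.25, (1, 1): 0.30}
        cohort, S = _cell_cohort(2000, probs, seed=8)
        ci = bootstrap_ci(cohort, S.astype(float), B=400, seed=2)
        assert ci.or_low > 1.0

    def test_bootstrap_and_wald_intervals_overlap(self):
        """On a well-behaved large-n problem the percentile-bootstrap and
        Wald CIs for the interaction log-OR agree substantially
        (interval Jaccard >= 0.5)."""
        probs = {(0, 0): 0.30, (0, 1): 0.15, (1, 0): 0.22, (1, 1): 0.30}
        cohort, S = _cell_cohort(1500, probs, seed=14)
        fit = fit_interaction_model(cohort, S.astype(float))
        ci = bootstrap_ci(cohort, S.astype(float), B=600, seed=3)
        named = fit.table.set_index("term").loc["amiodarone_x_subgroup"]
        lo_w, hi_w = np.log(named.ci_low), np.log(named.ci_high)
        lo_b, hi_b = np.log(ci.or_low), np.log(ci.or_high)
        inter = max(0.0, min(hi_w, hi_b) - max(lo_w, lo_b))
        union = max(hi_w, hi_b) - min(lo_w, lo_b)
        assert inter / union >= 0.5

    def test_too_small_b_rejected(self):
        probs = {(t, s): 0.4 for t in (0, 1) for s in (0, 1)}
        cohort, S = _cell_cohort(50, probs, seed=9)
        with pytest.raises(ConfigurationError):
            bootstrap_ci(cohort, S.astype(float), B=50, seed=0)


class TestPermutation:
    def test_add_one_formula(self):
        assert perm_pvalue(2.0, np.full(19, -1.0)) == pytest.approx(1 / 20)
        assert perm_pvalue(0.0, np.zeros(19)) == 1.0  # ties count as >= observed
        assert perm_pvalue(-5.0, np.zeros(99)) == 1.0
        assert perm_pvalue(5.0, np.arange(99.0)) == pytest.approx((1 + 94) / 100)

    def test_minimum_b_enforced(self, null_cohort_1000):
        cohort, _ = null_cohort_1000
        with pytest.raises(ConfigurationError):
            permutation_test(cohort, PipelineConfig(), B=5, seed=0)

    def test_strong_heterogeneity_rejects(self, default_cohort_2333):
        """The one-sided test detects the planted differential effect."""
        cohort, _ = default_cohort_2333
        cfg = PipelineConfig(
            propensity=PropensityConfig(n_lambda=15, lambda_min_ratio=1e-3),
            benefit=BenefitConfig(n_lambda=15, lambda_min_ratio=1e-3),
            cv=CVConfig(outer_k=3, inner_k=3),
            infer=InferenceConfig(), seed=2,
        )
        res = permutation_test(cohort, cfg, B=99, seed=5)
        assert res.p_value <= 0.05
        assert res.observed > 0

    def test_permutation_is_deterministic(self, null_cohort_1000):
        cohort, _ = null_cohort_1000
        cfg = PipelineConfig(
            propensity=PropensityConfig(n_lambda=12, lambda_min_ratio=1e-2),
            benefit=BenefitConfig(n_lambda=12, lambda_min_ratio=1e-2),
            cv=CVConfig(outer_k=2, inner_k=2), seed=3,
        )
        r1 = permutation_test(cohort, cfg, B=19, seed=7)
        r2 = permutation_test(cohort, cfg, B=19, seed=7)
        assert r1.p_value == r2.p_value
        np.testing.assert_array_equal(r1.permuted, r2.permuted)


class TestOutcomeTable:
    def test_planted_proportions_reproduced(self):
        probs = {(0, 0): 0.30, (0, 1): 0.09, (1, 0): 0.28, (1, 1): 0.15}
        cohort, S = _cell_cohort(500, probs, seed=10)
        table = subgroup_outcome_table(cohort, S.astype(float))
        y = cohort.y_neuro
        for _, row in table.iterrows():
            s = 1.0 if row.subgroup == "benefit" else 0.0
            t = 1 if row.arm == "amiodarone_pos" else 0
            mask = (S == s) & (cohort.T == t)
            assert row.n == mask.sum()
            assert row.neuro_prop == pytest.approx(y[mask].mean())

    def test_counts_conserve_cohort_size(self, default_cohort_2333):
        cohort, _ = default_cohort_2333
        S = (np.arange(cohort.n) % 2).astype(float)
        table = subgroup_outcome_table(cohort, S)
        assert table.n.sum() == cohort.n
        assert ((table.neuro_prop.dropna() >= 0) & (table.neuro_prop.dropna() <= 1)).all()

    def test_single_populated_cell(self):
        probs = {(t, s): 0.4 for t in (0, 1) for s in (0, 1)}
        cohort, _ = _cell_cohort(20, probs, seed=11)
        cohort = cohort.with_treatment(np.ones(cohort.n, dtype=int))
        table = subgroup_outcome_table(cohort, np.ones(cohort.n))
        populated = table[table.n > 0]
        assert len(populated) == 1
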