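"""Differential-effect inference across score-defined subgroups.

The estimand is the subgroup-by-treatment interaction odds ratio from an
unpenalized multivariable logistic model of the 30-day outcome on the
baseline covariates, the in-hospital co-interventions (ECPR, PCI, mild
therapeutic hypothermia), treatment, subgroup membership, and the
treatment x subgroup product. Uncertainty comes from a nonparametric
patient-level bootstrap (percentile CI; subgroup labels travel with the
resampled patients); the one-sided p-value comes from a permutation test
in which treatment labels are permuted and *every* model-fitting stage —
propensity, benefit score, nested-CV scoring, subgroup assignment and
the interaction model — is re-run from scratch per permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._solver import newton_logistic
from .cohort import AnalysisCohort, COINTERVENTION_COLUMNS, COVARIATE_COLUMNS
from .config import PipelineConfig, child_seed
from .crossval import cross_validated_scores, make_cv_plan
from .exceptions import ConfigurationError, EstimationError
from .score import ScoreAssignment

__all__ = [
    "InteractionFit", "BootstrapCI", "PermutationResult",
    "fit_interaction_model", "bootstrap_ci", "permutation_test",
    "subgroup_outcome_table", "pipeline_interaction", "perm_pvalue",
]

INTERACTION_TERMS = (
    ["intercept"] + COVARIATE_COLUMNS + COINTERVENTION_COLUMNS
    + ["amiodarone", "subgroup", "amiodarone_x_subgroup"]
)


@dataclass
class InteractionFit:
    table: pd.DataFrame                  # term, coef, or_, ci_low, ci_high (Wald)
    cov: np.ndarray = field(repr=False)
    outcome: str = "neuro"
    n: int = 0
    converged: bool = True
    separated: bool = False
    degenerate_split: bool = False

    @property
    def interaction_log_or(self) -> float:
        return float(self.table.set_index("term").loc["amiodarone_x_subgroup", "coef"])

    @property
    def interaction_or(self) -> float:
        return float(np.exp(self.interaction_log_or))

    @classmethod
    def degenerate(cls, outcome: str, n: int) -> "InteractionFit":
        """Single-subgroup partition: no heterogeneity identified.

        The interaction is unestimable, and the scoring stage found no
        differential structure, so the statistic is fixed at log-OR 0.
        """
        p = len(INTERACTION_TERMS)
        coef = np.full(p, np.nan)
        coef[-1] = 0.0
        table = pd.DataFrame({
            "term": INTERACTION_TERMS, "coef": coef, "or_": np.exp(coef),
            "ci_low": np.nan, "ci_high": np.nan, "se": np.nan,
        })
        return cls(table=table, cov=np.full((p, p), np.nan), outcome=outcome,
                   n=n, converged=True, separated=False, degenerate_split=True)


@dataclass
class BootstrapCI:
    or_low: float
    or_high: float
    B: int
    n_dropped: int
    seed: int
    log_or_stats: np.ndarray = field(repr=False)


@dataclass
class PermutationResult:
    observed: float                      # interaction log-OR
    permuted: np.ndarray
    p_value: float
    B: int
    seed: int
    n_redrawn: int = 0


def _subgroup_vector(subgroup, n: int) -> np.ndarray:
    if isinstance(subgroup, ScoreAssignment):
        s = subgroup.benefit_mask.astype(float)
    else:
        s = np.asarray(subgroup)
        if s.dtype.kind in "UO":
            s = (s == "benefit").astype(float)
        else:
            s = s.astype(float)
    if s.shape[0] != n:
        raise ConfigurationError("subgroup labels do not match cohort size")
    return s


def _interaction_design(cohort: AnalysisCohort, s: np.ndarray) -> np.ndarray:
    X = cohort.X.to_numpy(dtype=float)
    C = cohort.cointerventions.to_numpy(dtype=float)
    T = cohort.T.astype(float)
    return np.column_stack([np.ones(cohort.n), X, C, T, s, T * s])


def _implausible(beta, D) -> bool:
    """Backstop separation check: a slope above 10 log-odds per sd of its
    column has run away even if the step-size test nominally converged."""
    sd = D.std(axis=0)
    return bool(np.max(np.abs(beta[1:]) * sd[1:]) > 10.0)


def fit_interaction_model(cohort: AnalysisCohort, subgroup, outcome: str = "neuro") -> InteractionFit:
    """Unpenalized logistic MLE of the adjusted subgroup-by-treatment model.

    Raises on an empty subgroup or treatment arm; (quasi-)separation is
    flagged on the result rather than raised, so callers can drop or
    redraw degenerate replicates.
    """
    s = _subgroup_vector(subgroup, cohort.n)
    y = cohort.outcome(outcome).astype(float)
    T = cohort.T
    if s.min() == s.max():
        raise EstimationError("both subgroups must be non-empty")
    if T.min() == T.max():
        raise EstimationError("both treatment arms must be non-empty")

    D = np.ascontiguousarray(_interaction_design(cohort, s))
    w = np.ones(cohort.n)
    beta, cov, converged, separated = newton_logistic(D, y, w, 100, 1e-8)
    separated = separated or _implausible(beta, D)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    z = norm.ppf(0.975)
    # exponent clipped: near-separated fits have huge SEs and the OR bound
    # is effectively infinite anyway
    table = pd.DataFrame({
        "term": INTERACTION_TERMS,
        "coef": beta,
        "or_": np.exp(np.clip(beta, -500, 500)),
        "ci_low": np.exp(np.clip(beta - z * se, -500, 500)),
        "ci_high": np.exp(np.clip(beta + z * se, -500, 500)),
        "se": se,
    })
    return InteractionFit(table=table, cov=cov, outcome=outcome, n=cohort.n,
                          converged=bool(converged), separated=bool(separated))


def bootstrap_ci(
    cohort: AnalysisCohort,
    subgroup,
    outcome: str = "neuro",
    B: int = 10000,
    seed: int = 0,
    refit_full: bool = False,
    config: PipelineConfig | None = None,
) -> BootstrapCI:
    """Percentile bootstrap 95% CI for the interaction OR.

    By default the cross-validated subgroup labels are treated as fixed
    patient attributes and only the interaction model is refit per
    replicate. With ``refit_full`` the entire scoring pipeline is re-run
    on each resample (requires ``config``); this is far more expensive
    and is exposed for sensitivity analysis.
    """
    if B < 100:
        raise ConfigurationError("bootstrap needs B >= 100")
    s = _subgroup_vector(subgroup, cohort.n)
    y = cohort.outcome(outcome).astype(float)
    D = np.ascontiguousarray(_interaction_design(cohort, s))
    rng = np.random.default_rng(seed)
    n = cohort.n
    j_int = len(INTERACTION_TERMS) - 1
    stats = np.empty(B)
    dropped = 0
    w1 = np.ones(n)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        Db = np.ascontiguousarray(D[idx])
        if refit_full:
            if config is None:
                raise ConfigurationError("refit_full bootstrap requires a pipeline config")
            sub = _resample_cohort(cohort, idx)
            try:
                fit, _ = pipeline_interaction(
                    sub, config, outcome=outcome,
                    seed=child_seed(seed, "boot_refit", b))
            except EstimationError:
                stats[b] = np.nan
                dropped += 1
                continue
            if fit.separated or not fit.converged:
                stats[b] = np.nan
                dropped += 1
                continue
            stats[b] = fit.interaction_log_or
            continue
        if yb.min() == yb.max() or Db[:, j_int].min() == Db[:, j_int].max():
            stats[b] = np.nan
            dropped += 1
            continue
        beta, _cov, converged, separated = newton_logistic(Db, yb, w1, 100, 1e-8)
        if separated or not converged or _implausible(beta, Db):
            stats[b] = np.nan
            dropped += 1
            continue
        stats[b] = beta[j_int]
    good = stats[np.isfinite(stats)]
    if good.size == 0:
        raise EstimationError(
            "every bootstrap replicate was degenerate; the cohort is too "
            "small or too sparse for the interaction model")
    if dropped > 0.2 * B:
        warnings.warn(
            f"bootstrap: {dropped}/{B} degenerate replicates dropped; CI may be unstable",
            stacklevel=2)
    lo, hi = np.percentile(good, [2.5, 97.5])
    return BootstrapCI(or_low=float(np.exp(lo)), or_high=float(np.exp(hi)),
                       B=B, n_dropped=dropped, seed=seed, log_or_stats=stats)


def _resample_cohort(cohort: AnalysisCohort, idx: np.ndarray) -> AnalysisCohort:
    frame = cohort.frame.iloc[idx].reset_index(drop=True)
    return AnalysisCohort(
        patient_id=cohort.patient_id[idx],
        X=cohort.X.iloc[idx].reset_index(drop=True),
        T=cohort.T[idx],
        y_neuro=cohort.y_neuro[idx],
        y_surv=cohort.y_surv[idx],
        cointerventions=cohort.cointerventions.iloc[idx].reset_index(drop=True),
        frame=frame,
        encoding=cohort.encoding,
    )


def pipeline_interaction(
    cohort: AnalysisCohort,
    config: PipelineConfig,
    outcome: str = "neuro",
    seed: int | None = None,
):
    """Run scoring pipeline end to end: nested-CV scores -> subgroups ->
    interaction fit. Returns ``(InteractionFit, ScoreAssignment)``.

    The score is always built on the scoring outcome of the config
    (``config.benefit.outcome``); ``outcome`` selects which 30-day outcome
    the interaction model evaluates against those subgroups, mirroring a
    secondary-outcome analysis with the primary-outcome score.
    """
    seed = config.seed if seed is None else seed
    plan = make_cv_plan(cohort.n, config.cv.outer_k, config.cv.inner_k,
                        seed=child_seed(seed, "cv_plan"), stratify=cohort.T)
    assignment = cross_validated_scores(cohort, plan, config,
                                        outcome=config.benefit.outcome)
    if assignment.single_subgroup:
        # constant-sign score: the scoring stage identified no
        # heterogeneity, so the interaction statistic is 0 by convention
        return InteractionFit.degenerate(outcome, cohort.n), assignment
    fit = fit_interaction_model(cohort, assignment, outcome=outcome)
    return fit, assignment


def perm_pvalue(observed: float, permuted: np.ndarray) -> float:
    """Add-one permutation p-value, p = (1 + #{perm >= obs}) / (1 + B)."""
    permuted = np.asarray(permuted, dtype=float)
    return float((1 + np.sum(permuted >= observed)) / (1 + permuted.size))


def permutation_test(
    cohort: AnalysisCohort,
    config: PipelineConfig,
    outcome: str = "neuro",
    B: int = 999,
    seed: int = 0,
    observed: float | None = None,
) -> PermutationResult:
    """One-sided permutation test of the treatment-subgroup interaction.

    Treatment labels are permuted across patients; the whole pipeline is
    refit from scratch per permutation, and the statistic is the
    interaction log-OR. The alternative is a *larger* interaction — more
    treatment benefit in the positive-score subgroup. Degenerate permuted
    fits are redrawn (up to ``config.infer.max_redraws`` each).
    """
    if B < 19:
        raise ConfigurationError("permutation test needs B >= 19")
    if observed is None:
        fit, _ = pipeline_interaction(cohort, config, outcome=outcome,
                                      seed=child_seed(seed, "perm_observed"))
        observed = fit.interaction_log_or
    rng = np.random.default_rng(child_seed(seed, "perm_draws"))
    permuted = np.empty(B)
    n_redrawn = 0
    for b in range(B):
        ok = False
        for _try in range(config.infer.max_redraws + 1):
            T_perm = rng.permutation(cohort.T)
            perm_cohort = cohort.with_treatment(T_perm, update_frame=False)
            try:
                fit_b, _ = pipeline_interaction(
                    perm_cohort, config, outcome=outcome,
                    seed=child_seed(seed, "perm_refit", b, _try))
            except EstimationError:
                n_redrawn += 1
                continue
            if fit_b.separated or not fit_b.converged:
                n_redrawn += 1
                continue
            permuted[b] = fit_b.interaction_log_or
            ok = True
            break
        if not ok:
            raise EstimationError(
                f"permutation {b}: no non-degenerate refit in "
                f"{config.infer.max_redraws + 1} attempts")
    return PermutationResult(
        observed=float(observed), permuted=permuted,
        p_value=perm_pvalue(observed, permuted), B=B, seed=seed,
        n_redrawn=n_redrawn,
    )


def subgroup_outcome_table(cohort: AnalysisCohort, subgroup) -> pd.DataFrame:
    """Outcome proportions in the 2 (arm) x 2 (subgroup) cells, both outcomes."""
    s = _subgroup_vector(subgroup, cohort.n)
    rows = []
    for sub_label, sub_val in (("benefit", 1.0), ("no_benefit", 0.0)):
        for arm_label, arm_val in (("amiodarone_pos", 1), ("amiodarone_neg", 0)):
            mask = (s == sub_val) & (cohort.T == arm_val)
            n_cell = int(mask.sum())
            row = {"subgroup": sub_label, "arm": arm_label, "n": n_cell}
            for oname, y in (("neuro", cohort.y_neuro), ("survival", cohort.y_surv)):
                k = int(y[mask].sum()) if n_cell else 0
                row[f"{oname}_count"] = k
                row[f"{oname}_prop"] = k / n_cell if n_cell else float("nan")
            rows.append(row)
    return pd.DataFrame(rows)
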