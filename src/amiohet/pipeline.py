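"""End-to-end orchestration: validate -> exclude/encode -> score -> infer.

`run_full_analysis` ties the stages together and emits a JSON-serializable
report plus a per-patient score CSV; every number in the report is
re-derivable from the serialized config and the input CSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import apply_exclusions, read_cohort_csv, summarize_cohort, validate_frame
from .config import PipelineConfig, child_seed
from .crossval import cross_validated_scores, make_cv_plan
from .exceptions import EstimationError, ValidationError
from .inference import (bootstrap_ci, fit_interaction_model, permutation_test,
                        subgroup_outcome_table)
from .propensity import compute_weights, fit_propensity
from .score import fit_benefit_model

logger = logging.getLogger("amiohet")

__all__ = ["run_full_analysis", "validate_input"]


def validate_input(source) -> list[str]:
    """Schema report for a cohort CSV (or frame); returns violations."""
    if isinstance(source, pd.DataFrame):
        frame = source
    else:
        try:
            frame = read_cohort_csv(source)
        except (ValidationError, pd.errors.EmptyDataError) as exc:
            return [str(exc) if not isinstance(exc, pd.errors.EmptyDataError) else "no records"]
    return validate_frame(frame)


def run_full_analysis(source, config: PipelineConfig | None = None,
                      outdir=None) -> dict:
    """Run the whole analysis on a cohort CSV path or raw DataFrame.

    Stages: schema validation, exclusions + encoding, full-data benefit
    model (descriptive), nested-CV scoring and subgroup assignment,
    adjusted interaction model with bootstrap CI and from-scratch
    permutation test for each configured outcome. Returns the report
    dict; with ``outdir`` also writes ``report.json``, ``scores.csv``
    and ``config.yaml``.
    """
    config = config or PipelineConfig()
    config.validate()
    frame = source if isinstance(source, pd.DataFrame) else read_cohort_csv(source)

    problems = [p for p in validate_frame(frame) if not p.startswith("column 'exclusion")]
    hard = [p for p in problems if not p.endswith("(they will be excluded as missing_data)")]
    if hard:
        raise ValidationError("input failed validation: " + "; ".join(hard[:10]))

    cohort, tally = apply_exclusions(frame)
    logger.info("exclusions: %s", tally.as_dict())
    summary = summarize_cohort(cohort)

    X = cohort.X.to_numpy(dtype=float)

    # descriptive full-data scoring model (the reported coefficients);
    # subgroup inference below uses only the leakage-free nested-CV scores
    pfit = fit_propensity(
        X, cohort.T, cv_folds=config.propensity.cv_folds,
        seed=child_seed(config.seed, "full_propensity"),
        lambda_rule=config.propensity.lambda_rule,
        truncation=config.propensity.truncation,
        n_lambda=config.propensity.n_lambda,
        lambda_min_ratio=config.propensity.lambda_min_ratio,
    )
    weights = compute_weights(pfit, cohort.T, config.propensity.truncation)
    bmodel = fit_benefit_model(
        cohort.X, cohort.T, cohort.outcome(config.benefit.outcome), weights,
        cv_folds=config.benefit.cv_folds,
        seed=child_seed(config.seed, "full_benefit"),
        lambda_rule=config.benefit.lambda_rule, outcome=config.benefit.outcome,
        n_lambda=config.benefit.n_lambda,
        lambda_min_ratio=config.benefit.lambda_min_ratio,
    )
    logger.info("propensity lambda=%.5g, benefit lambda=%.5g", pfit.lambda_, bmodel.lambda_)

    plan = make_cv_plan(cohort.n, config.cv.outer_k, config.cv.inner_k,
                        seed=child_seed(config.seed, "cv_plan"), stratify=cohort.T)
    assignment = cross_validated_scores(cohort, plan, config)
    n_benefit = int(assignment.benefit_mask.sum())

    report = {
        "software": {"package": "amiohet", "version": __version__},
        "config": config.to_dict(),
        "flow": tally.as_dict(),
        "table1": summary.to_dict(orient="records"),
        "propensity": {
            "lambda": pfit.lambda_,
            "coefficients": dict(zip(["intercept"] + list(cohort.X.columns),
                                     map(float, pfit.coefficients))),
        },
        "benefit_model": bmodel.to_dict(),
        "subgroup_split": {
            "benefit": n_benefit,
            "no_benefit": cohort.n - n_benefit,
            "benefit_pct": 100.0 * n_benefit / cohort.n if cohort.n else float("nan"),
            "single_subgroup": assignment.single_subgroup,
        },
        "subgroup_outcomes": subgroup_outcome_table(cohort, assignment).to_dict(orient="records"),
        "outcomes": {},
    }

    for outcome in config.outcomes:
        try:
            report["outcomes"][outcome] = _infer_outcome(cohort, assignment, outcome, config)
        except EstimationError as exc:
            # degenerate designs (e.g. constant covariates within arm) cannot
            # support the interaction model; report the diagnosis instead of
            # discarding the cohort-level results
            logger.warning("%s: inference not estimable: %s", outcome, exc)
            report["outcomes"][outcome] = {"estimation_error": str(exc)}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        pd.DataFrame({
            "patient_id": cohort.patient_id,
            "cv_score": assignment.score,
            "subgroup": assignment.subgroup,
        }).to_csv(outdir / "scores.csv", index=False)
        config.to_yaml(outdir / "config.yaml")
    return report


def _infer_outcome(cohort, assignment, outcome, config: PipelineConfig) -> dict:
    ifit = fit_interaction_model(cohort, assignment, outcome=outcome)
    ci = bootstrap_ci(
        cohort, assignment, outcome=outcome, B=config.infer.bootstrap_B,
        seed=child_seed(config.seed, "bootstrap", 0 if outcome == "neuro" else 1),
        refit_full=config.infer.bootstrap_refit_full, config=config,
    )
    perm = permutation_test(
        cohort, config, outcome=outcome, B=config.infer.perm_B,
        seed=child_seed(config.seed, "permutation", 0 if outcome == "neuro" else 1),
        observed=ifit.interaction_log_or,
    )
    logger.info("%s: OR_interaction=%.3f [%.3f, %.3f], one-sided p=%.4g",
                outcome, ifit.interaction_or, ci.or_low, ci.or_high, perm.p_value)
    return {
        "or_table": ifit.table.drop(columns="se").to_dict(orient="records"),
        "interaction_or": ifit.interaction_or,
        "bootstrap_ci": [ci.or_low, ci.or_high],
        "bootstrap_dropped": ci.n_dropped,
        "permutation_p_one_sided": perm.p_value,
        "permutation_B": perm.B,
        "converged": ifit.converged,
        "separated": ifit.separated,
    }
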