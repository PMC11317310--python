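# Methods

`amiohet` implements a subgroup-identification analysis for differential
treatment response in observational registry data, specialized to
amiodarone administration in adult out-of-hospital cardiac arrest (OHCA)
patients presenting with a shockable rhythm at hospital arrival. This
note records the model, the estimation choices, what the synthetic data
do and do not emulate, and the numerical conventions.

## The estimand and the scoring model

For covariates x (pre-hospital, Utstein-style), treatment T ∈ {0, 1}
(amiodarone) and a binary 30-day outcome Y (favorable neurological
status, CPC 1–2; secondarily survival), the individual treatment effect
is ITE(x) = P(Y=1 | x, T=1) − P(Y=1 | x, T=0). The package estimates a
*linear benefit score* s(x) = β₀ + βᵀx whose sign classifies patients:
s(x) ≥ 0 → "benefit" subgroup, s(x) < 0 → "no benefit".

Estimation uses the modified-covariate device: the working linear
predictor is (2T−1)·(β₀ + βᵀx), i.e. every working covariate (including
the intercept column) is multiplied by ±1 according to treatment, and
the model is fit by minimizing the weighted, lasso-penalized logistic
loss

  (1/n) Σᵢ wᵢ log(1 + exp(−(2Yᵢ−1)(2Tᵢ−1)(β₀ + βᵀxᵢ))) + λ‖β‖₁,

with the intercept unpenalized. The weights wᵢ = 1/(Tᵢêᵢ + (1−Tᵢ)(1−êᵢ))
are the inverse probability of the *received* treatment, built from a
propensity model ê(x) that is itself a lasso-penalized logistic
regression of T on x with its penalty chosen by K-fold cross-validation.
The population minimizer of the unrestricted weighted loss satisfies
2·expit(f*(x)) − 1 = ITE(x), so sign(f*) = sign(ITE); the linear
restriction makes the fitted score an interpretable bedside equation at
the cost of an approximation discussed under Limitations.

Why this construction: regressing Y on (x, T, x·T) directly forces the
lasso to spend its budget on prognostic main effects before it can touch
the interactions; the modified-covariate trick removes the main effects
from the optimization target so the penalty acts on the treatment-effect
structure alone.

## Pipeline stages

1. **Exclusions** (`cohort.apply_exclusions`): patients < 18 years,
   other antiarrhythmic use, records unlinkable to pre-hospital data,
   any missing field (complete-case). A record matching several reasons
   is tallied once under the first reason in that order, so the tally
   partitions the excluded set.
2. **Encoding** (`cohort.encode_covariates`): age (years),
   male sex, call-to-arrival interval (minutes), traumatic cause,
   witnessed arrest, bystander CPR, defibrillation count dummies
   (1–2 and ≥3 against a "0 times" reference), hypothermia at arrival
   (measured ≤ 34 °C *or* unmeasurably low), pre-hospital epinephrine.
3. **Propensity + weights** (`propensity`): CV-lasso logistic fit;
   fitted probabilities truncated to [ε, 1−ε], ε = 0.01 by default, to
   bound the weights (wᵢ ≤ 100) for bootstrap stability.
4. **Benefit score** (`score`): weighted modified-covariate CV-lasso as
   above; scoring and subgroup assignment at cutoff 0 (a score of
   exactly 0 is classified "benefit").
5. **Nested CV** (`crossval`): outer folds stratified by treatment
   (default 5) hold out patients for scoring; inside each outer training
   set, the propensity model and the benefit model are re-fit with their
   penalties re-tuned by inner CV (default 10-fold). Every patient's
   score therefore comes from models that never saw their own outcome or
   treatment.
6. **Inference** (`inference`): an unpenalized multivariable logistic
   model of the outcome on the ten baseline covariates, the in-hospital
   co-interventions (ECPR, PCI, mild therapeutic hypothermia), T, the
   subgroup indicator S and T·S. The interaction odds ratio exp(β_{T·S})
   is the headline quantity. Its 95% CI is a percentile bootstrap over
   patients (default B = 10,000; labels travel with resampled patients;
   only the interaction model is refit per replicate — a full-pipeline
   bootstrap is available via `infer.bootstrap_refit_full`). The
   one-sided p-value comes from a permutation test (default B = 999):
   treatment labels are permuted and *every* stage — propensity,
   weights, benefit model, nested-CV scoring, subgroup assignment,
   interaction model — is re-run from scratch per permutation; the
   alternative is a larger interaction log-OR (more benefit in the
   positive-score subgroup), and p = (1 + #{perm ≥ obs}) / (1 + B).

Secondary-outcome analyses reuse the subgroups defined by the
primary-outcome score: `pipeline_interaction(..., outcome="survival")`
scores with the configured scoring outcome and evaluates the survival
interaction against those labels.

### Degenerate partitions

When the cross-validated score falls entirely on one side of the cutoff
(typical under a null where the CV-selected benefit model shrinks every
slope to zero and the per-fold intercepts share a sign), the interaction
is unestimable and the scoring stage has identified no heterogeneity;
the pipeline then fixes the interaction statistic at log-OR 0. This
keeps the permutation test defined under the null and only makes it more
conservative (ties at 0 count against rejection).

## Tunable parameters

| key | default | meaning |
|---|---|---|
| `propensity.cv_folds`, `benefit.cv_folds` | 10 | K for penalty CV in standalone fits |
| `propensity.lambda_rule`, `benefit.lambda_rule` | `min` | deviance-minimizing λ; `1se` for the parsimonious rule |
| `propensity.truncation` | 0.01 | ê clamp, bounds weights at 1/ε |
| `*.n_lambda`, `*.lambda_min_ratio` | 60, glmnet rule | λ-path resolution and depth |
| `cv.outer_k`, `cv.inner_k` | 5, 10 | nested-CV fold counts |
| `infer.bootstrap_B` | 10000 | bootstrap replicates |
| `infer.perm_B` | 999 | permutations |
| `seed` | 0 | master seed; all stage seeds derive from it |

All randomness descends from the master seed via
`SeedSequence((master, crc32(tag), *indices))`, so fold plans, per-fold
penalty CV, the bootstrap and every permutation refit are independently
and exactly reproducible.

## The penalized solver

Both fitting stages share one solver (`penalized` /`_solver`): IRLS with
a glmnet-style quadratic approximation and cyclic coordinate descent,
warm-started along a log-spaced λ path, with observation weights
(normalized to mean 1 so λ is scale-free), per-feature penalty factors
(rescaled to sum to the number of columns), and internal standardization
(weighted sd; centering only when a free intercept exists) with
coefficients returned on the original scale. The benefit stage passes
the signed intercept column with penalty factor 0 and centers the
covariates first — an exact reparametrization absorbed by the
unpenalized signed intercept that removes the near-collinearity between
that column and signed raw-scale covariates (without it, coordinate
descent zigzags badly). Agreement with R glmnet on identical problems is
~1e−7; agreement with a BFGS optimizer of the exact loss at λ = 0 is
below 1e−5 (both are test oracles).

Numerical conventions: IRLS variance floor 1e−5; coordinate-change
convergence tolerance 1e−7 (standardized scale); ties at λ_max give the
exact null model. The unpenalized interaction model uses damped
Newton–Raphson with backtracking; (quasi-)separation is flagged when the
iteration stalls away from a stationary point with runaway linear
predictors, or when any slope exceeds 10 log-odds per column sd.
Separated bootstrap replicates are dropped and counted (a warning fires
above 20%); separated permutation refits are redrawn.

## The synthetic cohort generator

`simulate.generate_cohort` draws covariates independently with marginals
matching the study population (male 78.4%, witnessed 68.9%, bystander
CPR 49.3%, traumatic cause 6.7%, defibrillation 44.9/22.6/32.5%,
hypothermia 49.4%, epinephrine 45.8%; age truncated-normal median 67,
IQR 55–77; call-to-arrival log-normal median 28 min, IQR 22–35).
Treatment follows a logistic propensity whose defaults reproduce the
observed arm imbalances (more male, younger, more witnessed, far more
pre-hospital defibrillation among treated; ~49% treated overall).
Outcomes follow logit P(Y=1) = g(x) + (2T−1)·s_true(x)/2, which makes
sign(s_true) equal sign(ITE) exactly; survival shares the structure with
an intercept shift (+0.55 → ~21% vs ~14%). Co-interventions are drawn
downstream of T with strong positive dependence (ECPR ~27% → ~59%) and
by default do not feed back into outcomes — they are pure confounder
stress for the adjusted interaction model (`cointervention_outcome_coefs`
enables feedback). Coefficients apply to z-scored age and log-interval
by default (`coef_scale="raw"` switches to per-year/per-minute).

Default effect magnitudes are a design choice. The planted heterogeneity
(age +0.8, interval +0.65, witness −0.95, defib −0.8/−1.25, hypothermia
+0.65, epinephrine +0.65 on the z-scale, intercept +0.6) was calibrated
jointly with moderate prognostic effects so that the linear
modified-covariate score can actually recover the planted sign
structure: the asymptotic agreement ceiling (see Limitations) is ~0.90
under these defaults, and finite-sample agreement at n = 20,000 is
0.89–0.92 across seeds. The two deterministic fixtures
(`make_flow_fixture`, `make_table1_fixture`) are not simulations: they
are constructed tables whose exclusion-flag counts, per-arm category
counts and per-arm medians match the published patient flow and baseline
table exactly, with arbitrary (fixed) joint structure — they validate
the exclusion and summary arithmetic, nothing else.

What the generator does **not** emulate: real joint covariate dependence
(covariates are independent given the margins), time-to-event outcomes,
site effects, or informative missingness. Passing tests therefore show
that the pipeline recovers structure it was told the truth about under
clean conditions — not that the score would transport to a real
registry.

## Calibration experiments (design)

* **Type-I error.** The permutation test is exact under exchangeability.
  With the default observational generator, permuting T breaks the
  T–covariate and T–co-intervention dependence, so even under a null
  with no treatment effect the permutation distribution over-disperses
  and the test becomes conservative (0/40 rejections at α = 0.05 in a
  design probe) — valid, but not size-α. The two-sided calibration check
  therefore uses the exchangeable null (benefit coefficients zero,
  propensity flat, co-interventions independent of T), where the
  empirical size over 200 replicates of n = 1000 (B = 99, 2 outer / 2
  inner folds, 12-point λ path) must land in [0.02, 0.09].
* **Bootstrap coverage.** Outcomes are drawn from the interaction model
  itself with interaction OR 1.6 on synthetic covariates and fixed
  true-score subgroups; the percentile CI (B = 500) must cover the true
  OR in 92–98% of 200 replicates of n = 1000.

Problem sizes in the test suite (fold counts 2/2, λ paths of 12–20
points, B = 99–500, n = 600–20,000) are the package's chosen desk-scale
study conditions; the full-scale defaults (10 folds, B = 10,000/999)
remain the production configuration.

## Limitations

* **Linear-score ceiling.** The unrestricted minimizer of the weighted
  modified-covariate loss satisfies sign(f*) = sign(ITE) pointwise, but
  the best *linear* score approximates f*(x) = logit((1 + ITE(x))/2),
  which is a nonlinear transform whose effective weighting emphasizes
  patients with mid-range outcome probability. With strong prognostic
  main effects, the best linear score's zero set can deviate from
  {s_true = 0} for a nontrivial fraction of patients regardless of
  sample size (we measured an 84% agreement ceiling under 2×-stronger
  prognostic effects). Sign agreement is therefore an asymptotically
  biased measure of score quality under severe prognostic heterogeneity.
* **Conservatism of the permutation test in observational data**, as
  above; the p-values remain valid.
* The default bootstrap conditions on the cross-validated subgroup
  labels; it quantifies uncertainty in the interaction model given the
  labels, not in the scoring pipeline (use `bootstrap_refit_full` for
  the latter, at ~100× the cost).
* Percentages in summaries use round-half-up to one decimal, the
  registry-table convention; re-derived percentages can differ from
  naive banker's rounding in the last digit.
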