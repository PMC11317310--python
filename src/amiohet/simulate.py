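"""Synthetic OHCA-like cohort generation with known ground truth.

The generator emulates a registry of adult out-of-hospital cardiac
arrest patients with a shockable rhythm at hospital arrival:

* baseline covariates drawn independently with marginals matching the
  study population (e.g. 78.4% male, 68.9% witnessed, defibrillation
  counts 44.9/22.6/32.5% across 0 / 1-2 / >=3 attempts; age truncated
  normal with median 67 and IQR 55-77; call-to-arrival log-normal with
  median 28 min and IQR 22-35);
* treatment (amiodarone) assigned by a logistic propensity model e(x);
* binary 30-day outcomes (favorable neurological status CPC 1-2, and
  survival) drawn from a logistic model whose linear predictor is a
  prognostic part plus the treatment interaction (2T-1) * s(x) / 2,
  where s(x) is the true linear benefit score — so sign(s) equals the
  sign of the individual treatment effect exactly;
* in-hospital co-interventions (ECPR / PCI / mild therapeutic
  hypothermia) drawn downstream of treatment with positive dependence,
  mimicking the strong arm imbalance seen in practice; by default they
  do not feed back into outcomes (configurable).

Besides the stochastic generator, two deterministic fixtures reproduce
the published cohort-flow counts and baseline table of the motivating
study, so the exclusion and summary stages can be tested against exact
printed numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .cohort import COVARIATE_COLUMNS, EXCLUSION_COLUMNS, RAW_COLUMNS
from .exceptions import ConfigurationError

__all__ = [
    "CovariateMarginals", "SimulationConfig", "default_config",
    "generate_cohort", "make_flow_fixture", "make_table1_fixture",
]

_N_COV = len(COVARIATE_COLUMNS)  # 10 encoded covariates


@dataclass
class CovariateMarginals:
    """Target marginal distributions of the baseline covariates.

    Continuous targets are (median, (q1, q3)) pairs; age uses a truncated
    normal (IQR/1.349 gives the pre-truncation sd), call-to-arrival a
    log-normal (right-skewed duration). Binary/categorical fields are
    success probabilities; the three defibrillation probabilities must
    sum to 1.
    """

    age_median: float = 67.0
    age_iqr: tuple = (55.0, 77.0)
    age_bounds: tuple = (18.0, 100.0)
    call_median: float = 28.0
    call_iqr: tuple = (22.0, 35.0)
    p_male: float = 0.784
    p_trauma: float = 0.067
    p_witness: float = 0.689
    p_bystander: float = 0.493
    p_defib: tuple = (0.449, 0.226, 0.325)
    p_hypothermia: float = 0.494
    p_epi: float = 0.458

    def validate(self) -> None:
        probs = [self.p_male, self.p_trauma, self.p_witness, self.p_bystander,
                 self.p_hypothermia, self.p_epi, *self.p_defib]
        if any(not (0.0 < p < 1.0) for p in probs):
            raise ConfigurationError("all probability parameters must lie in (0, 1)")
        if abs(sum(self.p_defib) - 1.0) > 1e-9:
            raise ConfigurationError("defibrillation category probabilities must sum to 1")

    @property
    def age_sd(self) -> float:
        return (self.age_iqr[1] - self.age_iqr[0]) / 1.3489795003921634

    @property
    def call_log_mu(self) -> float:
        return float(np.log(self.call_median))

    @property
    def call_log_sd(self) -> float:
        return float(np.log(self.call_iqr[1] / self.call_iqr[0]) / 1.3489795003921634)


# Coefficient vectors are over [intercept] + COVARIATE_COLUMNS, applied to
# the design with age and call-to-arrival on the z-score scale by default
# (coef_scale="standardized"), or per-year / per-minute (coef_scale="raw").

def _default_propensity_coefs() -> np.ndarray:
    # treated arm: younger, more male, more witnessed, fewer trauma,
    # far more pre-hospital defibrillation (arm imbalances of the registry)
    return np.array([
        -0.86,   # intercept -> ~49% treated overall
        -0.15,   # age (z)
        0.35,    # sex male
        0.00,    # call-to-arrival (z)
        -1.50,   # trauma
        0.25,    # witness
        0.05,    # bystander
        0.55,    # defib 1-2
        1.05,    # defib >=3
        -0.05,   # hypothermia
        0.05,    # pre-hospital epinephrine
    ])


def _default_prognostic_coefs() -> np.ndarray:
    # favorable neurological outcome ~14% overall, classic Utstein
    # prognostic structure (witness/bystander help, delay/age/trauma hurt);
    # moderate magnitudes so the prognostic part does not swamp the
    # planted interaction (see the methods note on score recoverability)
    return np.array([
        -1.95,   # intercept
        -0.28,   # age (z)
        0.05,    # sex male
        -0.15,   # call-to-arrival (z)
        -0.70,   # trauma
        0.35,    # witness
        0.12,    # bystander
        0.08,    # defib 1-2
        0.03,    # defib >=3
        -0.22,   # hypothermia
        -0.40,   # pre-hospital epinephrine
    ])


def _default_benefit_coefs() -> np.ndarray:
    # planted treatment-effect heterogeneity: amiodarone helps more with
    # higher age, longer call-to-arrival interval, no witness, no
    # pre-hospital defibrillation, hypothermia, and epinephrine use
    return np.array([
        0.60,    # intercept -> score positive for roughly half the cohort
        0.80,    # age (z)
        0.00,    # sex male
        0.65,    # call-to-arrival (z)
        0.00,    # trauma
        -0.95,   # witness
        0.00,    # bystander
        -0.80,   # defib 1-2
        -1.25,   # defib >=3
        0.65,    # hypothermia
        0.65,    # pre-hospital epinephrine
    ])


def _default_cointervention_coefs() -> dict:
    # [intercept, treatment, *covariates]; control-arm rates ~25/15/14%
    # with strong positive treatment dependence (ECPR 25% -> ~56%)
    def vec(icept, t_coef, witness=0.0, age=0.0):
        v = np.zeros(2 + _N_COV)
        v[0] = icept
        v[1] = t_coef
        v[2 + COVARIATE_COLUMNS.index("age")] = age
        v[2 + COVARIATE_COLUMNS.index("witness")] = witness
        return v
    return {
        "ecpr": vec(-1.09, 1.33, witness=0.15, age=-0.25),
        "pci": vec(-1.73, 0.92, age=0.10),
        "mth": vec(-1.86, 0.70, witness=0.10),
    }


@dataclass
class SimulationConfig:
    """Full data-generating specification for one synthetic cohort."""

    n_patients: int = 2333
    marginals: CovariateMarginals = field(default_factory=CovariateMarginals)
    propensity_coefs: np.ndarray = field(default_factory=_default_propensity_coefs)
    prognostic_coefs: np.ndarray = field(default_factory=_default_prognostic_coefs)
    benefit_coefs: np.ndarray = field(default_factory=_default_benefit_coefs)
    cointervention_coefs: dict = field(default_factory=_default_cointervention_coefs)
    survival_intercept_shift: float = 0.55  # survival ~23% vs neuro ~14%
    cointervention_outcome_coefs: np.ndarray | None = None  # off by default
    coef_scale: str = "standardized"  # or "raw": age per year, call per minute
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        self.marginals.validate()
        for name in ("propensity_coefs", "prognostic_coefs", "benefit_coefs"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (_N_COV + 1,):
                raise ConfigurationError(
                    f"{name} must have length {_N_COV + 1} (intercept + encoded covariates),"
                    f" got {v.shape}")
        for key, v in self.cointervention_coefs.items():
            v = np.asarray(v, dtype=float)
            if v.shape != (_N_COV + 2,):
                raise ConfigurationError(
                    f"cointervention_coefs[{key!r}] must have length {_N_COV + 2}")
        if self.coef_scale not in ("standardized", "raw"):
            raise ConfigurationError("coef_scale must be 'standardized' or 'raw'")


    def to_dict(self) -> dict:
        d = {
            "n_patients": self.n_patients,
            "marginals": dict(self.marginals.__dict__),
            "propensity_coefs": list(map(float, self.propensity_coefs)),
            "prognostic_coefs": list(map(float, self.prognostic_coefs)),
            "benefit_coefs": list(map(float, self.benefit_coefs)),
            "cointervention_coefs": {k: list(map(float, v))
                                     for k, v in self.cointervention_coefs.items()},
            "survival_intercept_shift": self.survival_intercept_shift,
            "cointervention_outcome_coefs": (
                None if self.cointervention_outcome_coefs is None
                else list(map(float, self.cointervention_outcome_coefs))),
            "coef_scale": self.coef_scale,
            "seed": self.seed,
        }
        for key in ("age_iqr", "age_bounds", "call_iqr", "p_defib"):
            d["marginals"][key] = list(d["marginals"][key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        marg = {k: (tuple(v) if isinstance(v, list) else v)
                for k, v in d.pop("marginals", {}).items()}
        cfg = cls(
            n_patients=int(d.pop("n_patients", 2333)),
            marginals=CovariateMarginals(**marg),
            propensity_coefs=np.asarray(d.pop("propensity_coefs",
                                              _default_propensity_coefs()), dtype=float),
            prognostic_coefs=np.asarray(d.pop("prognostic_coefs",
                                              _default_prognostic_coefs()), dtype=float),
            benefit_coefs=np.asarray(d.pop("benefit_coefs",
                                           _default_benefit_coefs()), dtype=float),
            cointervention_coefs={k: np.asarray(v, dtype=float) for k, v in
                                  d.pop("cointervention_coefs",
                                        _default_cointervention_coefs()).items()},
            survival_intercept_shift=float(d.pop("survival_intercept_shift", 0.55)),
            cointervention_outcome_coefs=(
                None if d.get("cointervention_outcome_coefs") is None
                else np.asarray(d["cointervention_outcome_coefs"], dtype=float)),
            coef_scale=d.pop("coef_scale", "standardized"),
            seed=int(d.pop("seed", 0)),
        )
        d.pop("cointervention_outcome_coefs", None)
        if d:
            raise ConfigurationError(f"unknown SimulationConfig keys: {sorted(d)}")
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        import yaml
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_config(n_patients: int = 2333, seed: int = 0, **overrides) -> SimulationConfig:
    cfg = SimulationConfig(n_patients=n_patients, seed=seed)
    for key, val in overrides.items():
        if not hasattr(cfg, key):
            raise ConfigurationError(f"unknown SimulationConfig field {key!r}")
        setattr(cfg, key, val)
    cfg.validate()
    return cfg


def _design_for_coefs(X: pd.DataFrame, cfg: SimulationConfig) -> np.ndarray:
    """Design matrix on the scale the coefficient vectors refer to."""
    Z = X[COVARIATE_COLUMNS].to_numpy(dtype=float).copy()
    if cfg.coef_scale == "standardized":
        m = cfg.marginals
        ia = COVARIATE_COLUMNS.index("age")
        ic = COVARIATE_COLUMNS.index("call_to_arrival_min")
        Z[:, ia] = (Z[:, ia] - m.age_median) / m.age_sd
        Z[:, ic] = (np.log(Z[:, ic]) - m.call_log_mu) / m.call_log_sd
    return Z


def generate_cohort(config: SimulationConfig):
    """Draw one synthetic cohort; returns ``(raw_frame, truth_frame)``.

    ``raw_frame`` follows the cohort data dictionary (no exclusions set);
    ``truth_frame`` carries the per-patient true propensity, true benefit
    score and true individual treatment effect on the primary outcome.
    Fully reproducible for a fixed config (including seed).
    """
    config.validate()
    m = config.marginals
    n = config.n_patients
    rng = np.random.default_rng(config.seed)

    a, b = ((m.age_bounds[0] - m.age_median) / m.age_sd,
            (m.age_bounds[1] - m.age_median) / m.age_sd)
    age = truncnorm.rvs(a, b, loc=m.age_median, scale=m.age_sd, size=n, random_state=rng)
    call = np.exp(rng.normal(m.call_log_mu, m.call_log_sd, size=n))

    defib_cat = rng.choice(np.array(["0", "1_2", "3plus"]), size=n, p=list(m.p_defib))
    raw = pd.DataFrame({
        "patient_id": np.arange(1, n + 1),
        "age": np.round(age, 1),
        "sex": (rng.random(n) < m.p_male).astype(int),
        "call_to_arrival_min": np.round(call, 1),
        "cause_trauma": (rng.random(n) < m.p_trauma).astype(int),
        "witness": (rng.random(n) < m.p_witness).astype(int),
        "bystander": (rng.random(n) < m.p_bystander).astype(int),
        "defib_category": defib_cat,
        "hypothermia_arrival": (rng.random(n) < m.p_hypothermia).astype(int),
        "prehosp_epi": (rng.random(n) < m.p_epi).astype(int),
    })

    X = pd.DataFrame({
        "age": raw["age"].to_numpy(dtype=float),
        "sex_male": raw["sex"].to_numpy(),
        "call_to_arrival_min": raw["call_to_arrival_min"].to_numpy(dtype=float),
        "cause_trauma": raw["cause_trauma"].to_numpy(),
        "witness": raw["witness"].to_numpy(),
        "bystander": raw["bystander"].to_numpy(),
        "defib_1or2": (defib_cat == "1_2").astype(int),
        "defib_3plus": (defib_cat == "3plus").astype(int),
        "hypothermia": raw["hypothermia_arrival"].to_numpy(),
        "prehosp_epi": raw["prehosp_epi"].to_numpy(),
    })
    Z = _design_for_coefs(X, config)
    Z1 = np.column_stack([np.ones(n), Z])

    e_true = expit(Z1 @ np.asarray(config.propensity_coefs, dtype=float))
    T = (rng.random(n) < e_true).astype(int)
    raw["amiodarone"] = T

    prog = Z1 @ np.asarray(config.prognostic_coefs, dtype=float)
    s_true = Z1 @ np.asarray(config.benefit_coefs, dtype=float)
    sign = 2.0 * T - 1.0

    co = {}
    for key in ("ecpr", "pci", "mth"):
        v = np.asarray(config.cointervention_coefs[key], dtype=float)
        eta = v[0] + v[1] * T + Z @ v[2:]
        co[key] = (rng.random(n) < expit(eta)).astype(int)
        raw[key] = co[key]

    co_part = np.zeros(n)
    if config.cointervention_outcome_coefs is not None:
        cc = np.asarray(config.cointervention_outcome_coefs, dtype=float)
        co_part = cc[0] * co["ecpr"] + cc[1] * co["pci"] + cc[2] * co["mth"]

    eta_neuro = prog + sign * s_true / 2.0 + co_part
    eta_surv = eta_neuro + config.survival_intercept_shift
    raw["cpc30"] = (rng.random(n) < expit(eta_neuro)).astype(int)
    raw["survival30"] = (rng.random(n) < expit(eta_surv)).astype(int)
    raw = raw[RAW_COLUMNS]

    # the true ITE fixes the co-intervention path at its realized value
    ite = expit(prog + s_true / 2.0 + co_part) - expit(prog - s_true / 2.0 + co_part)
    truth = pd.DataFrame({
        "patient_id": raw["patient_id"],
        "true_propensity": e_true,
        "true_benefit_score": s_true,
        "true_ite": ite,
    })
    return raw, truth


# ---------------------------------------------------------------------------
# Deterministic fixtures reproducing the published flow and baseline table
# ---------------------------------------------------------------------------

# per-arm counts: (amiodarone+ n=1138, amiodarone- n=1195)
_TABLE1_COUNTS = {
    "sex": (936, 894),
    "cause_trauma": (28, 129),
    "witness": (833, 775),
    "bystander": (576, 575),
    "hypothermia_arrival": (554, 599),
    "prehosp_epi": (528, 541),
    "ecpr": (636, 301),
    "pci": (351, 179),
    "mth": (270, 161),
    "survival30": (277, 257),
    "cpc30": (158, 177),
}
_TABLE1_DEFIB = {"0": (413, 634), "1_2": (240, 287), "3plus": (485, 274)}
_TABLE1_N = (1138, 1195)
_TABLE1_AGE = (65.0, 70.0)
_TABLE1_CALL = (28.0, 29.0)


def _ones_at(n: int, count: int, offset: int) -> np.ndarray:
    """0/1 vector with ``count`` ones placed cyclically starting at ``offset``."""
    v = np.zeros(n, dtype=int)
    idx = (offset + np.arange(count)) % n
    v[idx] = 1
    return v


def make_table1_fixture() -> pd.DataFrame:
    """Deterministic 2333-record cohort matching the published baseline table.

    Every per-arm categorical count and both outcome counts are exact;
    continuous values are constant at the printed per-arm median (so the
    medians are exact while the joint structure is arbitrary but fixed).
    """
    frames = []
    for arm, n_arm in enumerate(_TABLE1_N):  # arm 0 = amiodarone(+), 1 = (-)
        cols = {"amiodarone": np.full(n_arm, 1 - arm)}
        cols["age"] = np.full(n_arm, _TABLE1_AGE[arm])
        cols["call_to_arrival_min"] = np.full(n_arm, _TABLE1_CALL[arm])
        offset = 0
        for col, counts in _TABLE1_COUNTS.items():
            cols[col] = _ones_at(n_arm, counts[arm], offset * 97)
            offset += 1
        # defibrillation: contiguous blocks give exactly one level per row
        c0, c12 = _TABLE1_DEFIB["0"][arm], _TABLE1_DEFIB["1_2"][arm]
        defib = np.empty(n_arm, dtype=object)
        defib[:c0] = "0"
        defib[c0:c0 + c12] = "1_2"
        defib[c0 + c12:] = "3plus"
        cols["defib_category"] = defib
        frames.append(pd.DataFrame(cols))
    frame = pd.concat(frames, ignore_index=True)
    frame["patient_id"] = np.arange(1, len(frame) + 1)
    return frame[RAW_COLUMNS]


def make_flow_fixture() -> pd.DataFrame:
    """Deterministic 2958-record cohort reproducing the published patient flow.

    Exactly 14 pediatric, 227 other-antiarrhythmic, 308 unlinkable and 76
    missing-data records (disjoint; 625 excluded in total) precede the 2333
    analyzable records, which are the baseline-table fixture.
    """
    counts = {"pediatric": 14, "other_antiarrhythmic": 227,
              "unlinkable": 308, "missing_data": 76}
    n_excl = sum(counts.values())

    excl = make_table1_fixture().iloc[:n_excl].copy().reset_index(drop=True)
    for col in EXCLUSION_COLUMNS:
        excl[col] = 0
    pos = 0
    for (reason, cnt), col in zip(counts.items(), EXCLUSION_COLUMNS):
        excl.loc[pos:pos + cnt - 1, col] = 1
        if reason == "pediatric":
            excl.loc[pos:pos + cnt - 1, "age"] = 10.0
        if reason == "missing_data":
            excl.loc[pos:pos + cnt - 1, "witness"] = np.nan
        pos += cnt

    retained = make_table1_fixture()
    for col in EXCLUSION_COLUMNS:
        retained[col] = 0
    frame = pd.concat([excl, retained], ignore_index=True)
    frame["patient_id"] = np.arange(1, len(frame) + 1)
    return frame[RAW_COLUMNS + EXCLUSION_COLUMNS]
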