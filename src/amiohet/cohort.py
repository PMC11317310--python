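"""Cohort construction: exclusion criteria, covariate encoding, summaries.

The tabular interchange format (the "data dictionary") is a flat CSV with
one row per patient. Binary variables are coded 1/0; the defibrillation
count is a three-level categorical (``0``, ``1_2``, ``3plus``, reference
level "0 times"); hypothermia at hospital arrival means a measured body
temperature <= 34 degC *or* a temperature too low to measure (an
unmeasurable temperature is treated as hypothermic).

Exclusions follow the study design: patients under 18 years, patients
given other antiarrhythmic drugs, records that cannot be linked to the
pre-hospital (Utstein) data, and records with any missing field. A record
matching several reasons is tallied once, under the first reason in that
order, so the tally is an exact partition of the excluded records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "RAW_COLUMNS", "EXCLUSION_COLUMNS", "COVARIATE_COLUMNS", "CONTINUOUS_COLUMNS",
    "COINTERVENTION_COLUMNS", "DEFIB_LEVELS", "EXCLUSION_ORDER",
    "AnalysisCohort", "ExclusionTally", "EncodingMetadata",
    "apply_exclusions", "encode_covariates", "summarize_cohort",
    "read_cohort_csv", "write_cohort_csv", "validate_frame", "round_pct",
]

RAW_COLUMNS = [
    "patient_id", "age", "sex", "call_to_arrival_min", "cause_trauma",
    "witness", "bystander", "defib_category", "hypothermia_arrival",
    "prehosp_epi", "amiodarone", "ecpr", "pci", "mth", "cpc30", "survival30",
]
EXCLUSION_COLUMNS = [
    "exclusion_pediatric", "exclusion_other_antiarrhythmic",
    "exclusion_unlinkable", "exclusion_missing_data",
]
EXCLUSION_ORDER = ["pediatric", "other_antiarrhythmic", "unlinkable", "missing_data"]

COVARIATE_COLUMNS = [
    "age", "sex_male", "call_to_arrival_min", "cause_trauma", "witness",
    "bystander", "defib_1or2", "defib_3plus", "hypothermia", "prehosp_epi",
]
CONTINUOUS_COLUMNS = ["age", "call_to_arrival_min"]
COINTERVENTION_COLUMNS = ["ecpr", "pci", "mth"]
DEFIB_LEVELS = ("0", "1_2", "3plus")

_BINARY_RAW = [
    "sex", "cause_trauma", "witness", "bystander", "hypothermia_arrival",
    "prehosp_epi", "amiodarone", "ecpr", "pci", "mth", "cpc30", "survival30",
]


def round_pct(count: int, total: int) -> float:
    """Percentage to one decimal, round-half-up (registry table convention)."""
    if total == 0:
        return float("nan")
    q = (Decimal(int(count)) * 100 / Decimal(int(total))).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(q)


@dataclass
class ExclusionTally:
    """Counts per exclusion reason (first-reason attribution) plus retained."""

    pediatric: int = 0
    other_antiarrhythmic: int = 0
    unlinkable: int = 0
    missing_data: int = 0
    retained: int = 0

    @property
    def excluded(self) -> int:
        return self.pediatric + self.other_antiarrhythmic + self.unlinkable + self.missing_data

    def as_dict(self) -> dict:
        return {
            "pediatric": self.pediatric,
            "other_antiarrhythmic": self.other_antiarrhythmic,
            "unlinkable": self.unlinkable,
            "missing_data": self.missing_data,
            "excluded_total": self.excluded,
            "retained": self.retained,
        }


@dataclass
class EncodingMetadata:
    """Standardization transform for continuous columns (identity if unset)."""

    standardized: bool
    means: dict = field(default_factory=dict)
    scales: dict = field(default_factory=dict)

    def inverse_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        out = X.copy()
        for col, m in self.means.items():
            out[col] = out[col] * self.scales[col] + m
        return out


@dataclass
class AnalysisCohort:
    """Encoded analysis-ready cohort: design matrix X, treatment T, outcomes."""

    patient_id: np.ndarray
    X: pd.DataFrame
    T: np.ndarray
    y_neuro: np.ndarray
    y_surv: np.ndarray
    cointerventions: pd.DataFrame
    frame: pd.DataFrame = field(repr=False)
    encoding: EncodingMetadata = field(default_factory=lambda: EncodingMetadata(False))

    @property
    def n(self) -> int:
        return len(self.patient_id)

    def outcome(self, name: str) -> np.ndarray:
        if name == "neuro":
            return self.y_neuro
        if name == "survival":
            return self.y_surv
        raise ValidationError(f"unknown outcome {name!r}; expected 'neuro' or 'survival'")

    def with_treatment(self, T_new: np.ndarray, update_frame: bool = True) -> "AnalysisCohort":
        """Copy of the cohort with a replaced treatment vector (for permutations).

        ``update_frame=False`` skips copying the raw frame (the modeling
        stages never read it), which matters inside permutation loops.
        """
        T_new = np.asarray(T_new, dtype=np.int64)
        if T_new.shape[0] != self.n:
            raise ValidationError("replacement treatment vector has wrong length")
        if not update_frame:
            return replace(self, T=T_new)
        frame = self.frame.copy()
        frame["amiodarone"] = T_new
        return replace(self, T=T_new, frame=frame)

    def with_outcome(self, name: str, y_new: np.ndarray) -> "AnalysisCohort":
        y_new = np.asarray(y_new, dtype=np.int64)
        if name == "neuro":
            return replace(self, y_neuro=y_new)
        if name == "survival":
            return replace(self, y_surv=y_new)
        raise ValidationError(f"unknown outcome {name!r}")


def _as01(series: pd.Series, col: str) -> np.ndarray:
    vals = pd.to_numeric(series, errors="coerce")
    bad = ~vals.isin([0, 1])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(f"column {col!r}: non-binary value at row {row}")
    return vals.to_numpy(dtype=np.int64)


def _derive_reason_masks(records: pd.DataFrame) -> dict:
    n = len(records)
    masks = {r: np.zeros(n, dtype=bool) for r in EXCLUSION_ORDER}
    for reason, col in zip(EXCLUSION_ORDER, EXCLUSION_COLUMNS):
        if col in records.columns:
            masks[reason] |= pd.to_numeric(records[col], errors="coerce").fillna(0).to_numpy() == 1
    if "age" in records.columns:
        age = pd.to_numeric(records["age"], errors="coerce")
        masks["pediatric"] |= (age < 18).to_numpy()
    required = [c for c in RAW_COLUMNS if c in records.columns and c != "patient_id"]
    if required:
        masks["missing_data"] |= records[required].isna().any(axis=1).to_numpy()
    return masks


def apply_exclusions(records: pd.DataFrame, standardize: bool = False):
    """Filter a raw cohort by the study's exclusion criteria and encode it.

    Returns ``(AnalysisCohort, ExclusionTally)``. An empty input yields an
    empty cohort with a zero tally.
    """
    records = records.reset_index(drop=True)
    n = len(records)
    masks = _derive_reason_masks(records)

    attributed = np.zeros(n, dtype=bool)
    tally = ExclusionTally()
    for reason in EXCLUSION_ORDER:
        hit = masks[reason] & ~attributed
        setattr(tally, reason, int(hit.sum()))
        attributed |= masks[reason]
    retained = records.loc[~attributed].reset_index(drop=True)
    tally.retained = len(retained)

    cohort = _build_cohort(retained, standardize=standardize)
    return cohort, tally


def _build_cohort(frame: pd.DataFrame, standardize: bool = False) -> AnalysisCohort:
    n = len(frame)
    if n == 0:
        X = pd.DataFrame(columns=COVARIATE_COLUMNS, dtype=float)
        co = pd.DataFrame(columns=COINTERVENTION_COLUMNS, dtype=int)
        return AnalysisCohort(
            patient_id=np.array([], dtype=np.int64), X=X,
            T=np.array([], dtype=np.int64), y_neuro=np.array([], dtype=np.int64),
            y_surv=np.array([], dtype=np.int64), cointerventions=co, frame=frame,
        )
    X, meta = encode_covariates(frame, standardize=standardize)
    co = pd.DataFrame({c: _as01(frame[c], c) for c in COINTERVENTION_COLUMNS})
    return AnalysisCohort(
        patient_id=pd.to_numeric(frame["patient_id"]).to_numpy(dtype=np.int64),
        X=X,
        T=_as01(frame["amiodarone"], "amiodarone"),
        y_neuro=_as01(frame["cpc30"], "cpc30"),
        y_surv=_as01(frame["survival30"], "survival30"),
        cointerventions=co,
        frame=frame.reset_index(drop=True),
        encoding=meta,
    )


def encode_covariates(frame: pd.DataFrame, standardize: bool = False):
    """Encode raw baseline fields into the model design matrix.

    Dummy-codes defibrillation against the "0 times" reference; derives
    the hypothermia indicator from ``body_temp_c`` (<= 34 or unmeasurable
    -> 1) when ``hypothermia_arrival`` is absent. With ``standardize``,
    continuous columns are centered/scaled and the transform recorded in
    the returned :class:`EncodingMetadata`.
    """
    n = len(frame)
    out = {}
    out["age"] = pd.to_numeric(frame["age"], errors="coerce").to_numpy(dtype=float)
    out["sex_male"] = _as01(frame["sex"], "sex")
    out["call_to_arrival_min"] = pd.to_numeric(
        frame["call_to_arrival_min"], errors="coerce").to_numpy(dtype=float)
    for col in ("cause_trauma", "witness", "bystander", "prehosp_epi"):
        out[col] = _as01(frame[col], col)

    defib = frame["defib_category"].astype(str).str.strip()
    defib = defib.str.replace(r"\.0$", "", regex=True)  # tolerate numeric CSV round-trip
    bad = ~defib.isin(DEFIB_LEVELS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"column 'defib_category': unknown level {defib.iloc[row]!r} at row {row}"
        )
    out["defib_1or2"] = (defib == "1_2").to_numpy(dtype=np.int64)
    out["defib_3plus"] = (defib == "3plus").to_numpy(dtype=np.int64)

    if "hypothermia_arrival" in frame.columns:
        out["hypothermia"] = _as01(frame["hypothermia_arrival"], "hypothermia_arrival")
    elif "body_temp_c" in frame.columns:
        temp = pd.to_numeric(frame["body_temp_c"], errors="coerce")
        out["hypothermia"] = ((temp <= 34.0) | temp.isna()).to_numpy(dtype=np.int64)
    else:
        raise ValidationError("need 'hypothermia_arrival' or 'body_temp_c' column")

    X = pd.DataFrame({c: out[c] for c in COVARIATE_COLUMNS}, dtype=float)
    meta = EncodingMetadata(standardized=standardize)
    if standardize and n > 1:
        for col in CONTINUOUS_COLUMNS:
            m = float(X[col].mean())
            s = float(X[col].std(ddof=0)) or 1.0
            X[col] = (X[col] - m) / s
            meta.means[col] = m
            meta.scales[col] = s
    return X, meta


_SUMMARY_BINARY = [
    ("sex", "Sex, male"),
    ("cause_trauma", "Cause for CA, trauma"),
    ("witness", "Witness, yes"),
    ("bystander", "Bystander, yes"),
    ("hypothermia_arrival", "Hypothermia at hospital arrival, yes"),
    ("prehosp_epi", "Pre-hospital epinephrine administration, yes"),
    ("ecpr", "ECPR"),
    ("pci", "PCI"),
    ("mth", "MTH"),
    ("survival30", "Survival at 30 days"),
    ("cpc30", "Good neurological outcome (CPC <=2) at 30 days"),
]


def summarize_cohort(cohort) -> pd.DataFrame:
    """Baseline-characteristics summary by treatment arm and overall.

    Returns a long-form frame with columns ``variable``, ``group``
    (``amiodarone_pos`` / ``amiodarone_neg`` / ``overall``), ``n``,
    ``count``, ``pct`` (one decimal, round-half-up) for categorical rows
    and ``median``/``q1``/``q3`` for continuous rows.
    """
    frame = cohort.frame if isinstance(cohort, AnalysisCohort) else cohort
    T = pd.to_numeric(frame["amiodarone"]).to_numpy()
    groups = {
        "amiodarone_pos": frame.loc[T == 1],
        "amiodarone_neg": frame.loc[T == 0],
        "overall": frame,
    }
    rows = []
    for gname, g in groups.items():
        ng = len(g)
        for col in ("age", "call_to_arrival_min"):
            v = pd.to_numeric(g[col], errors="coerce")
            rows.append({
                "variable": col, "group": gname, "n": ng,
                "median": float(v.median()), "q1": float(v.quantile(0.25)),
                "q3": float(v.quantile(0.75)),
            })
        for col, _label in _SUMMARY_BINARY:
            c = int((pd.to_numeric(g[col], errors="coerce") == 1).sum())
            rows.append({"variable": col, "group": gname, "n": ng,
                         "count": c, "pct": round_pct(c, ng)})
        defib = g["defib_category"].astype(str).str.strip()
        for level in DEFIB_LEVELS:
            c = int((defib == level).sum())
            rows.append({"variable": f"defib_{level}", "group": gname, "n": ng,
                         "count": c, "pct": round_pct(c, ng)})
    return pd.DataFrame(rows)


def validate_frame(frame: pd.DataFrame) -> list[str]:
    """Data-dictionary conformance check; returns a list of violations."""
    problems: list[str] = []
    if len(frame) == 0:
        return ["no records"]
    for col in RAW_COLUMNS:
        if col not in frame.columns:
            problems.append(f"missing column: {col}")
    if problems:
        return problems
    flagged = np.zeros(len(frame), dtype=bool)
    for col in EXCLUSION_COLUMNS:
        if col in frame.columns:
            flagged |= pd.to_numeric(frame[col], errors="coerce").fillna(0).to_numpy() == 1
    for col in _BINARY_RAW:
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = ~vals.isin([0, 1]) & ~flagged
        for row in np.flatnonzero(bad.to_numpy())[:5]:
            problems.append(f"column {col!r}: invalid value {frame[col].iloc[row]!r} at row {row}")
    defib = frame["defib_category"].astype(str).str.strip().str.replace(r"\.0$", "", regex=True)
    bad = ~defib.isin(DEFIB_LEVELS) & ~flagged & ~frame["defib_category"].isna().to_numpy()
    for row in np.flatnonzero(bad.to_numpy())[:5]:
        problems.append(
            f"column 'defib_category': invalid level {frame['defib_category'].iloc[row]!r} at row {row}"
        )
    for col in ("age", "call_to_arrival_min"):
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = (vals < 0) & ~flagged
        for row in np.flatnonzero(bad.to_numpy())[:5]:
            problems.append(f"column {col!r}: negative value at row {row}")
    missing = frame[RAW_COLUMNS].isna().any(axis=1) & ~flagged
    n_missing = int(missing.sum())
    if n_missing:
        problems.append(
            f"{n_missing} unflagged record(s) with missing data "
            "(they will be excluded as missing_data)"
        )
    return problems


def read_cohort_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"defib_category": str})
    missing = [c for c in RAW_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"cohort CSV missing columns: {missing}")
    return frame


def write_cohort_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)
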