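"""Patient cohort container, CSV round-trip, summary tables and
complete-case filtering.

A cohort is an ordered collection of patient records carrying clinical
covariates (age, sex, hypertension, tumor type and involvement, surgery
count, GTV volume), treatment doses, dose-volume summary metrics over the
optic apparatus (D_min, D_mean, D_max, D_1%, D_99%, all scalars in Gy_RBE),
follow-up and the graded optic-neuropathy outcome.  Records must satisfy the
study's hard constraints, most importantly the inclusion criterion of at
least 45 Gy_RBE maximum dose to the optic apparatus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import fisher_exact_test, rank_sum_test

__all__ = [
    "PatientRecord",
    "Cohort",
    "CohortSummary",
    "RowParseError",
    "read_cohort",
    "write_cohort",
    "summarize_cohort",
    "complete_case_filter",
    "covariate_frame",
    "CONTINUOUS_VARIABLES",
    "CATEGORICAL_VARIABLES",
    "SURGERY_DICHOTOMIES",
]

DEFAULT_MISSING_TOKEN = "NA"
DEFAULT_DOSE_TOLERANCE = 2.0  # Gy_RBE slack between prescription and component doses
MIN_OPTIC_DMAX = 45.0         # inclusion criterion, Gy_RBE

_TRISTATE = {"yes", "no"}


class RowParseError(ValueError):
    """A cohort CSV row that cannot be parsed, with row and field context."""


@dataclass
class PatientRecord:
    """One patient's covariates, dose metrics and outcome.

    ``hypertension`` and ``tumor_involvement`` are tri-state: ``"yes"``,
    ``"no"`` or ``None`` (missing).  ``rion_grade`` is the CTCAE grade of
    radiation-induced optic neuropathy, 0 meaning no event.
    """

    patient_id: str
    institution: str            # PSI | CPO
    tumor_type: str             # chordoma | chondrosarcoma
    age: float                  # years
    sex: str                    # F | M
    hypertension: str | None
    n_surgeries: int
    gtv_volume: float           # cc
    tumor_involvement: str | None
    prescription_dose: float    # Gy_RBE
    proton_dose: float
    photon_dose: float
    optic_dmin: float
    optic_dmean: float
    optic_dmax: float
    optic_d1: float
    optic_d99: float
    followup_months: float
    rion_grade: int
    modality_protons_only: bool
    modality_pbs: bool

    def validate(self, dose_tolerance: float = DEFAULT_DOSE_TOLERANCE) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        problems: list[str] = []
        if self.institution not in {"PSI", "CPO"}:
            problems.append(f"unknown institution '{self.institution}'")
        if self.tumor_type not in {"chordoma", "chondrosarcoma"}:
            problems.append(f"unknown tumor_type '{self.tumor_type}'")
        if self.sex not in {"F", "M"}:
            problems.append(f"unknown sex '{self.sex}'")
        for name in ("hypertension", "tumor_involvement"):
            v = getattr(self, name)
            if v is not None and v not in _TRISTATE:
                problems.append(f"{name} must be yes/no/missing, got '{v}'")
        if self.age < 18:
            problems.append(f"age {self.age} below adult inclusion (18)")
        if not 0 <= self.rion_grade <= 4:
            problems.append(f"rion_grade {self.rion_grade} outside 0..4")
        if self.n_surgeries < 0:
            problems.append("n_surgeries negative")
        if not self.optic_dmin <= self.optic_dmean <= self.optic_dmax:
            problems.append("dose ordering dmin <= dmean <= dmax violated")
        if not self.optic_d99 <= self.optic_d1 <= self.optic_dmax:
            problems.append("dose ordering d99 <= d1 <= dmax violated")
        if self.optic_dmax < MIN_OPTIC_DMAX:
            problems.append(
                f"optic_dmax {self.optic_dmax} below the {MIN_OPTIC_DMAX} Gy_RBE inclusion criterion"
            )
        if self.modality_protons_only and self.photon_dose != 0:
            problems.append("photon_dose must be 0 for proton-only treatment")
        if abs(self.proton_dose + self.photon_dose - self.prescription_dose) > dose_tolerance:
            problems.append("proton + photon dose inconsistent with prescription dose")
        return problems

    @property
    def rion_event(self) -> int:
        return int(self.rion_grade >= 1)


@dataclass
class Cohort:
    """Ordered collection of patient records with provenance tag."""

    records: list[PatientRecord]
    provenance: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("patient_id values must be unique within a cohort")

    @property
    def n(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, keep: Iterable[bool], provenance_suffix: str = "") -> "Cohort":
        recs = [r for r, k in zip(self.records, keep) if k]
        return Cohort(recs, provenance=self.provenance + provenance_suffix, meta=dict(self.meta))


_COLUMNS = [f.name for f in dc_fields(PatientRecord)]
_FLOAT_FIELDS = {
    "age", "gtv_volume", "prescription_dose", "proton_dose", "photon_dose",
    "optic_dmin", "optic_dmean", "optic_dmax", "optic_d1", "optic_d99",
    "followup_months",
}
_INT_FIELDS = {"n_surgeries", "rion_grade"}
_BOOL_FIELDS = {"modality_protons_only", "modality_pbs"}
_TRISTATE_FIELDS = {"hypertension", "tumor_involvement"}


def _parse_value(name: str, raw: str, missing_token: str, row: int):
    if name in _TRISTATE_FIELDS:
        if raw == missing_token or raw == "" or pd.isna(raw):
            return None
        return str(raw).strip().lower()
    if pd.isna(raw) or raw == missing_token:
        raise RowParseError(f"row {row}: field '{name}' is missing but not tri-state")
    try:
        if name in _FLOAT_FIELDS:
            return float(raw)
        if name in _INT_FIELDS:
            return int(float(raw))
        if name in _BOOL_FIELDS:
            s = str(raw).strip().lower()
            if s in {"true", "1", "yes"}:
                return True
            if s in {"false", "0", "no"}:
                return False
            raise ValueError(raw)
        return str(raw).strip()
    except (TypeError, ValueError) as exc:
        raise RowParseError(f"row {row}: cannot parse field '{name}' value '{raw}'") from exc


def read_cohort(
    path,
    schema: Mapping[str, str] | None = None,
    *,
    missing_token: str = DEFAULT_MISSING_TOKEN,
    dose_tolerance: float = DEFAULT_DOSE_TOLERANCE,
) -> Cohort:
    """Read a cohort CSV into validated records.

    ``schema`` optionally maps canonical field names to the file's column
    names.  Rows violating hard record invariants are rejected (not loaded);
    their row indices and reasons are kept in ``cohort.meta['rejected_rows']``.
    A missing required column raises ``KeyError``; an unparseable cell raises
    :class:`RowParseError` naming the row and field.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {name: (schema or {}).get(name, name) for name in _COLUMNS}
    for name, col in colmap.items():
        if col not in df.columns:
            raise KeyError(f"required column '{col}' (field '{name}') absent from {path}")

    records: list[PatientRecord] = []
    rejected: list[tuple[int, list[str]]] = []
    for i, row in df.iterrows():
        values = {name: _parse_value(name, row[colmap[name]], missing_token, int(i)) for name in _COLUMNS}
        rec = PatientRecord(**values)
        problems = rec.validate(dose_tolerance)
        if problems:
            rejected.append((int(i), problems))
        else:
            records.append(rec)
    cohort = Cohort(records, provenance=str(path))
    if rejected:
        cohort.meta["rejected_rows"] = rejected
    return cohort


def write_cohort(cohort: Cohort, path, *, missing_token: str = DEFAULT_MISSING_TOKEN) -> None:
    """Write a cohort to CSV; ``read_cohort`` of the result reproduces the
    records field-for-field (missing tri-state values become the token)."""
    rows = []
    for r in cohort.records:
        row = {}
        for name in _COLUMNS:
            v = getattr(r, name)
            if name in _TRISTATE_FIELDS and v is None:
                v = missing_token
            row[name] = v
        rows.append(row)
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Modeling covariates
# ---------------------------------------------------------------------------

SURGERY_DICHOTOMIES = ["n_surgeries_gt1", "n_surgeries_gt2", "n_surgeries_gt3", "n_surgeries_gt4"]

CONTINUOUS_VARIABLES = [
    "age", "n_surgeries", "gtv_volume", "prescription_dose", "proton_dose",
    "photon_dose", "optic_dmin", "optic_dmean", "optic_dmax", "optic_d1",
    "optic_d99", "followup_months",
]
CATEGORICAL_VARIABLES = [
    "sex", "hypertension", "tumor_involvement", "tumor_type",
    "modality_protons_only", "modality_pbs",
] + SURGERY_DICHOTOMIES


def covariate_frame(cohort: Cohort) -> pd.DataFrame:
    """Numeric covariate matrix for modeling, one row per record.

    Encoding: sex 1=female, tumor_type 1=chordoma, tri-state yes/no as 1/0
    with NaN for missing, surgery-count dichotomies as 0/1 indicators.  The
    binary event indicator (any-grade neuropathy) is in column ``rion``.
    """
    data = {}
    recs = cohort.records
    tri = {"yes": 1.0, "no": 0.0, None: np.nan}
    data["age"] = [r.age for r in recs]
    data["sex"] = [1.0 if r.sex == "F" else 0.0 for r in recs]
    data["hypertension"] = [tri[r.hypertension] for r in recs]
    data["tumor_involvement"] = [tri[r.tumor_involvement] for r in recs]
    data["tumor_type"] = [1.0 if r.tumor_type == "chordoma" else 0.0 for r in recs]
    data["n_surgeries"] = [float(r.n_surgeries) for r in recs]
    for k, name in enumerate(SURGERY_DICHOTOMIES, start=1):
        data[name] = [1.0 if r.n_surgeries > k else 0.0 for r in recs]
    for name in ("gtv_volume", "prescription_dose", "proton_dose", "photon_dose",
                 "optic_dmin", "optic_dmean", "optic_dmax", "optic_d1", "optic_d99",
                 "followup_months"):
        data[name] = [float(getattr(r, name)) for r in recs]
    data["modality_protons_only"] = [1.0 if r.modality_protons_only else 0.0 for r in recs]
    data["modality_pbs"] = [1.0 if r.modality_pbs else 0.0 for r in recs]
    data["rion"] = [float(r.rion_event) for r in recs]
    return pd.DataFrame(data, index=[r.patient_id for r in recs])


def complete_case_filter(cohort: Cohort, variables: Sequence[str]) -> Cohort:
    """Keep only records with non-missing values for every listed variable,
    preserving order.  Unknown variable names raise ``KeyError``."""
    if not variables:
        return Cohort(list(cohort.records), provenance=cohort.provenance, meta=dict(cohort.meta))
    frame = covariate_frame(cohort)
    for v in variables:
        if v not in frame.columns:
            raise KeyError(f"unknown variable '{v}'")
    keep = frame[list(variables)].notna().all(axis=1).to_numpy()
    return cohort.subset(keep)


# ---------------------------------------------------------------------------
# Summary (inter-institution comparison)
# ---------------------------------------------------------------------------

_SUMMARY_CONTINUOUS = [
    "age", "optic_dmin", "optic_dmax", "gtv_volume", "prescription_dose",
    "followup_months", "n_surgeries",
]
_SUMMARY_CATEGORICAL = [
    "tumor_type", "sex", "hypertension", "tumor_involvement",
    "modality_protons_only", "modality_pbs", "rion_case",
]


@dataclass
class CohortSummary:
    """Per-variable medians/ranges or category counts, optionally with an
    inter-institution p-value (rank-sum for continuous, Fisher exact for
    categorical; missing values excluded from the tests)."""

    n: int
    entries: dict

    def to_json(self) -> str:
        return json.dumps({"n": self.n, "entries": self.entries}, indent=2)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for var, e in self.entries.items():
            row = {"variable": var, "kind": e["kind"]}
            if e["kind"] == "continuous":
                row["summary"] = f"{e['median']:g} ({e['min']:g}-{e['max']:g})"
            else:
                row["summary"] = ", ".join(f"{k}: {v} ({p:.1f}%)" for (k, v, p) in e["counts"])
            row["p_value"] = e.get("p_value")
            rows.append(row)
        return pd.DataFrame(rows)


def _variable_values(cohort: Cohort, var: str):
    if var == "rion_case":
        return np.array([r.rion_event for r in cohort.records], dtype=object)
    if var in _TRISTATE_FIELDS:
        return np.array([getattr(r, var) for r in cohort.records], dtype=object)
    return np.array([getattr(r, var) for r in cohort.records], dtype=object)


def summarize_cohort(cohort: Cohort, group_by_institution: bool = False) -> CohortSummary:
    """Summary table over the standard characteristic set.

    Continuous variables are reported as median (min-max); categorical as
    counts with percentages of ``n`` (missing counted as its own level).
    When grouped by institution each variable additionally carries a
    two-sided p-value comparing PSI vs CPO.
    """
    if cohort.n < 1:
        raise ValueError("cannot summarize an empty cohort")
    inst = np.array([r.institution for r in cohort.records])
    if group_by_institution:
        for level in ("PSI", "CPO"):
            if not np.any(inst == level):
                raise ValueError(f"grouping level '{level}' has zero records")

    entries: dict = {}
    for var in _SUMMARY_CONTINUOUS:
        vals = np.array([float(getattr(r, var)) for r in cohort.records])
        e = {"kind": "continuous", "median": float(np.median(vals)),
             "min": float(vals.min()), "max": float(vals.max())}
        if group_by_institution:
            e["p_value"] = rank_sum_test(vals[inst == "PSI"], vals[inst == "CPO"])
        entries[var] = e

    for var in _SUMMARY_CATEGORICAL:
        vals = _variable_values(cohort, var)
        levels = sorted({("missing" if v is None else str(v)) for v in vals})
        labeled = np.array(["missing" if v is None else str(v) for v in vals])
        counts = [(lv, int(np.sum(labeled == lv)), 100.0 * np.sum(labeled == lv) / cohort.n)
                  for lv in levels]
        e = {"kind": "categorical", "counts": counts}
        if group_by_institution:
            mask = labeled != "missing"
            use_levels = [lv for lv in levels if lv != "missing"]
            if len(use_levels) >= 2:
                table = np.array([
                    [int(np.sum((labeled == lv) & (inst == g) & mask)) for g in ("PSI", "CPO")]
                    for lv in use_levels
                ])
                if np.all(table.sum(axis=1) >= 0) and table.sum() > 0:
                    try:
                        e["p_value"] = fisher_exact_test(table)
                    except ValueError:
                        e["p_value"] = None
        entries[var] = e

    return CohortSummary(n=cohort.n, entries=entries)
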