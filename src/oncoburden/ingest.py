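"""Admission-level ingest and cohort inclusion/exclusion.

Reads one-row-per-admission CSV files (a primary diagnosis plus up to 18
secondary ICD-10 diagnoses per admission, either semicolon-joined in one
column or spread over wide ``dx2..dx19`` columns), applies the eligibility
rules of the emulated hospital cohort — five cancer types, a diagnosis-date
window, histology exclusions, and removal of patients with too few
admissions — and collapses the survivors to one analysis row per patient.

Exclusion order is fixed (cancer type -> date window -> histology -> too few
admissions) so that every patient is counted under exactly one exclusion
stage and the flow-chart counts are reproducible.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "AdmissionRecord",
    "PatientRecord",
    "FilterReport",
    "CsvDialect",
    "InclusionRules",
    "SchemaError",
    "read_admissions",
    "admissions_from_frame",
    "apply_inclusion_exclusion",
    "collapse_to_patients",
    "patients_to_frame",
    "write_admissions_csv",
]

CANCER_TYPES = ("lung", "colon", "rectal", "breast", "gastric")
STAGES = ("0", "I", "II", "III", "IV")
TREATMENT_FLAGS = ("surgery", "chemotherapy", "radiotherapy", "targeted")
MAX_SECONDARY_DX = 18

_REQUIRED_COLUMNS = (
    "patient_id", "admission_date", "discharge_date", "age", "sex",
    "insured", "married", "residency", "cancer_type", "histology",
    "cancer_stage", "department", "primary_dx", "total_cost",
)


class SchemaError(ValueError):
    """The input file does not carry the documented column schema."""


@dataclass(frozen=True)
class AdmissionRecord:
    """One hospital admission of one patient."""

    patient_id: str
    admission_date: dt.date
    discharge_date: dt.date
    age: float
    sex: str
    insured: bool
    married: bool
    residency: str
    cancer_type: str
    histology: str
    cancer_stage: str
    department: str
    primary_dx: str
    secondary_dx: tuple[str, ...] = ()
    treatment_flags: frozenset[str] = frozenset()
    total_cost: float | None = None
    education: str = ""

    def __post_init__(self) -> None:
        if self.admission_date > self.discharge_date:
            raise ValueError(
                f"{self.patient_id}: admission_date after discharge_date")
        if len(self.secondary_dx) > MAX_SECONDARY_DX:
            raise ValueError(f"{self.patient_id}: secondary_dx overflow "
                             f"({len(self.secondary_dx)} > {MAX_SECONDARY_DX})")


@dataclass(frozen=True)
class PatientRecord:
    """Per-patient analysis row (demographics from the first admission)."""

    patient_id: str
    cancer_type: str
    histology: str
    age: float
    sex: str
    insured: bool
    married: bool
    residency: str
    education: str
    cancer_stage: str
    n_admissions: int
    first_admission_date: dt.date
    union_dx: frozenset[str]
    treatment_flags: frozenset[str]
    total_cost: float | None
    cost_missing: bool


@dataclass
class FilterReport:
    """Counts at each inclusion/exclusion stage; stages are exclusive."""

    input_admissions: int = 0
    input_patients: int = 0
    parse_errors: list[str] = field(default_factory=list)
    excluded_cancer_type: int = 0
    excluded_date_window: int = 0
    excluded_histology: int = 0
    excluded_single_admission: int = 0
    final_patients: int = 0
    warnings: list[str] = field(default_factory=list)

    def check(self) -> None:
        total = (self.excluded_cancer_type + self.excluded_date_window
                 + self.excluded_histology + self.excluded_single_admission
                 + self.final_patients)
        if total != self.input_patients:
            raise AssertionError(
                f"filter counts do not conserve patients: {total} != "
                f"{self.input_patients}")

    def to_dict(self) -> dict:
        return {
            "input_admissions": self.input_admissions,
            "input_patients": self.input_patients,
            "n_parse_errors": len(self.parse_errors),
            "parse_errors": list(self.parse_errors),
            "excluded_cancer_type": self.excluded_cancer_type,
            "excluded_date_window": self.excluded_date_window,
            "excluded_histology": self.excluded_histology,
            "excluded_single_admission": self.excluded_single_admission,
            "final_patients": self.final_patients,
            "warnings": list(self.warnings),
        }


@dataclass(frozen=True)
class CsvDialect:
    """Input CSV conventions.

    ``secondary_dx_layout`` is either ``"joined"`` (one ``secondary_dx``
    column, codes joined by ``joined_sep``) or ``"wide"`` (columns
    ``dx2..dx19``).
    """

    delimiter: str = ","
    secondary_dx_layout: str = "joined"
    joined_sep: str = ";"
    date_format: str = "%Y-%m-%d"


# Histology exclusions of the emulated cohort: special breast histologies and
# in-situ disease, colorectal non-adenocarcinoma histologies, small cell lung
# cancer; male breast cancer is excluded alongside them.
_DEFAULT_EXCLUDED_HISTOLOGY: dict[str, frozenset[str]] = {
    "breast": frozenset({"non-invasive breast cancer", "mucinous adenocarcinoma",
                         "medullary carcinoma", "adenoid cystic carcinoma",
                         "Paget's disease"}),
    "colon": frozenset({"lymphoma", "sarcoma", "squamous cell carcinoma"}),
    "rectal": frozenset({"lymphoma", "sarcoma", "squamous cell carcinoma"}),
    "lung": frozenset({"small cell lung cancer"}),
    "gastric": frozenset(),
}


@dataclass(frozen=True)
class InclusionRules:
    """Step-1 eligibility rules.

    ``window`` is half-open ``[start, end)`` on the diagnosis date (earliest
    admission). ``min_admissions`` removes patients observed only once; the
    optional ``require_pair_within_days`` additionally demands two admissions
    within that many days of each other.
    """

    cancer_types: frozenset[str] = frozenset(CANCER_TYPES)
    window_start: dt.date = dt.date(2017, 1, 1)
    window_end: dt.date = dt.date(2019, 11, 1)
    excluded_histology: dict[str, frozenset[str]] = field(
        default_factory=lambda: dict(_DEFAULT_EXCLUDED_HISTOLOGY))
    exclude_male_breast: bool = True
    min_admissions: int = 2
    require_pair_within_days: int | None = None


def _parse_bool(value: str) -> bool:
    v = str(value).strip().lower()
    if v in {"1", "true", "yes", "y"}:
        return True
    if v in {"0", "false", "no", "n"}:
        return False
    raise ValueError(f"cannot parse boolean from {value!r}")


def _parse_row(row: dict, dialect: CsvDialect) -> AdmissionRecord:
    adm = dt.datetime.strptime(row["admission_date"], dialect.date_format).date()
    dis = dt.datetime.strptime(row["discharge_date"], dialect.date_format).date()
    sex = row["sex"].strip().lower()
    if sex not in {"male", "female"}:
        raise ValueError(f"unknown sex {row['sex']!r}")
    stage = row["cancer_stage"].strip()
    if stage not in STAGES:
        raise ValueError(f"unknown cancer_stage {row['cancer_stage']!r}")
    ct = row["cancer_type"].strip().lower()
    if dialect.secondary_dx_layout == "joined":
        raw = (row.get("secondary_dx") or "").strip()
        codes = tuple(c.strip() for c in raw.split(dialect.joined_sep) if c.strip())
    else:
        codes = tuple(
            row[f"dx{i}"].strip()
            for i in range(2, 20)
            if row.get(f"dx{i}", "").strip())
    tx_raw = (row.get("treatments") or "").strip()
    flags = frozenset(t.strip() for t in tx_raw.split(";") if t.strip())
    unknown = flags - set(TREATMENT_FLAGS)
    if unknown:
        raise ValueError(f"unknown treatment flag(s) {sorted(unknown)}")
    cost_raw = (row.get("total_cost") or "").strip()
    cost = None if cost_raw in {"", "NA", "nan", "NaN"} else float(cost_raw)
    if cost is not None and cost < 0:
        raise ValueError(f"negative total_cost {cost}")
    return AdmissionRecord(
        patient_id=row["patient_id"].strip(),
        admission_date=adm,
        discharge_date=dis,
        age=float(row["age"]),
        sex=sex,
        insured=_parse_bool(row["insured"]),
        married=_parse_bool(row["married"]),
        residency=row["residency"].strip().lower(),
        cancer_type=ct,
        histology=row["histology"].strip(),
        cancer_stage=stage,
        department=row["department"].strip(),
        primary_dx=row["primary_dx"].strip(),
        secondary_dx=codes,
        treatment_flags=flags,
        total_cost=cost,
        education=(row.get("education") or "").strip(),
    )


def read_admissions(
    path: str | Path, dialect: CsvDialect | None = None
) -> tuple[list[AdmissionRecord], list[str]]:
    """Parse an admissions CSV.

    Returns ``(records, row_errors)``; malformed rows are collected as
    row-numbered diagnostics rather than aborting the read. A missing
    required column raises :class:`SchemaError`.
    """
    dialect = dialect or CsvDialect()
    path = Path(path)
    records: list[AdmissionRecord] = []
    errors: list[str] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        header = reader.fieldnames or []
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if dialect.secondary_dx_layout == "joined" and "secondary_dx" not in header:
            missing.append("secondary_dx")
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")
        for i, row in enumerate(reader, start=2):  # 1-based incl. header
            try:
                records.append(_parse_row(row, dialect))
            except (ValueError, KeyError) as exc:
                errors.append(f"row {i}: {exc}")
    return records, errors


def admissions_from_frame(frame: pd.DataFrame,
                          dialect: CsvDialect | None = None) -> list[AdmissionRecord]:
    """Convert an in-memory admissions table to records (strict: raises)."""
    dialect = dialect or CsvDialect()
    records = []
    for _, row in frame.iterrows():
        raw = {k: ("" if pd.isna(v) else str(v)) for k, v in row.items()}
        records.append(_parse_row(raw, dialect))
    return records


def write_admissions_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write an admissions table in the standard dialect (UTF-8, comma)."""
    frame.to_csv(path, index=False, float_format="%.2f")


def collapse_to_patients(
    admissions: Iterable[AdmissionRecord],
    warnings: list[str] | None = None,
) -> list[PatientRecord]:
    """One :class:`PatientRecord` per patient id.

    ``union_dx`` is the deduplicated union of all primary and secondary
    codes; cost is summed over observed admissions (``cost_missing`` flags
    any missing admission cost); demographics come from the first admission
    by date, with conflicts logged to ``warnings``.
    """
    by_patient: dict[str, list[AdmissionRecord]] = {}
    for a in admissions:
        by_patient.setdefault(a.patient_id, []).append(a)
    out: list[PatientRecord] = []
    for pid in sorted(by_patient):
        adms = sorted(by_patient[pid], key=lambda a: (a.admission_date,
                                                      a.discharge_date))
        first = adms[0]
        for other in adms[1:]:
            for attr in ("sex", "cancer_type", "residency", "insured",
                         "married", "education"):
                if getattr(other, attr) != getattr(first, attr):
                    if warnings is not None:
                        warnings.append(
                            f"{pid}: conflicting {attr} across admissions; "
                            "first admission wins")
                    break
        union = set()
        flags: set[str] = set()
        observed = 0.0
        any_observed = False
        any_missing = False
        for a in adms:
            union.add(a.primary_dx)
            union.update(a.secondary_dx)
            flags.update(a.treatment_flags)
            if a.total_cost is None:
                any_missing = True
            else:
                observed += a.total_cost
                any_observed = True
        out.append(PatientRecord(
            patient_id=pid,
            cancer_type=first.cancer_type,
            histology=first.histology,
            age=first.age,
            sex=first.sex,
            insured=first.insured,
            married=first.married,
            residency=first.residency,
            education=first.education,
            cancer_stage=first.cancer_stage,
            n_admissions=len(adms),
            first_admission_date=first.admission_date,
            union_dx=frozenset(union),
            treatment_flags=frozenset(flags),
            total_cost=round(observed, 2) if any_observed else None,
            cost_missing=any_missing,
        ))
    return out


def apply_inclusion_exclusion(
    admissions: Sequence[AdmissionRecord],
    rules: InclusionRules | None = None,
    parse_errors: Sequence[str] = (),
) -> tuple[list[PatientRecord], FilterReport]:
    """Apply the Step-1 eligibility rules patient by patient.

    Each patient is excluded at most once, at the first failing rule, in the
    fixed order cancer type -> date window -> histology -> too few
    admissions. Returns the retained patients and an exhaustive
    :class:`FilterReport`.
    """
    rules = rules or InclusionRules()
    report = FilterReport(input_admissions=len(admissions),
                          parse_errors=list(parse_errors))
    patients = collapse_to_patients(admissions, warnings=report.warnings)
    report.input_patients = len(patients)
    kept: list[PatientRecord] = []
    by_patient: dict[str, list[AdmissionRecord]] = {}
    for a in admissions:
        by_patient.setdefault(a.patient_id, []).append(a)
    for p in patients:
        if p.cancer_type not in rules.cancer_types:
            report.excluded_cancer_type += 1
            continue
        if not (rules.window_start <= p.first_admission_date < rules.window_end):
            report.excluded_date_window += 1
            continue
        excluded_hist = rules.excluded_histology.get(p.cancer_type, frozenset())
        male_breast = (rules.exclude_male_breast
                       and p.cancer_type == "breast" and p.sex == "male")
        if p.histology in excluded_hist or male_breast:
            report.excluded_histology += 1
            continue
        if p.n_admissions < rules.min_admissions:
            report.excluded_single_admission += 1
            continue
        if rules.require_pair_within_days is not None and p.n_admissions >= 2:
            dates = sorted(a.admission_date for a in by_patient[p.patient_id])
            gaps = [(b - a).days for a, b in zip(dates, dates[1:])]
            if min(gaps) > rules.require_pair_within_days:
                report.excluded_single_admission += 1
                continue
        kept.append(p)
    report.final_patients = len(kept)
    report.check()
    return kept, report


def patients_to_frame(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    """Patient records as a flat table (sets joined with ';')."""
    rows = []
    for p in patients:
        rows.append({
            "patient_id": p.patient_id,
            "cancer_type": p.cancer_type,
            "histology": p.histology,
            "age": p.age,
            "sex": p.sex,
            "insured": int(p.insured),
            "married": int(p.married),
            "residency": p.residency,
            "education": p.education,
            "cancer_stage": p.cancer_stage,
            "n_admissions": p.n_admissions,
            "first_admission_date": p.first_admission_date.isoformat(),
            "union_dx": ";".join(sorted(p.union_dx)),
            "treatments": ";".join(sorted(p.treatment_flags)),
            "total_cost": p.total_cost if p.total_cost is not None else float("nan"),
            "cost_missing": int(p.cost_missing),
        })
    columns = ["patient_id", "cancer_type", "histology", "age", "sex",
               "insured", "married", "residency", "education", "cancer_stage",
               "n_admissions", "first_admission_date", "union_dx",
               "treatments", "total_cost", "cost_missing"]
    return pd.DataFrame(rows, columns=columns)
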