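"""Data model, delimited-file readers/writers and configuration loading.

Input layout is "long": one lab measurement or one diagnosis event per row.
Dates are calendar dates (ISO-8601); same-day ordering preserves file order.
ICD-10 codes are normalized to uppercase, dot-free, at most 5 characters and
matched by prefix throughout the package.
"""

from __future__ import annotations

import csv
import datetime as dt
import logging
import re
from collections import Counter
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

log = logging.getLogger("fcs_screen.records_io")

SEXES = ("male", "female")

#: canonical unit per analyte; unknown analytes are accepted with any unit
CANONICAL_UNITS: Mapping[str, str] = {
    "TG": "mmol/L",
    "CHOL": "mmol/L",
    "GLU": "mmol/L",
    "NA": "mmol/L",
    "UREA": "mmol/L",
    "GPT": "U/L",
    "GGT": "U/L",
    "AMYL": "U/L",
    "ALP": "U/L",
    "HGB": "g/L",
    "MCHC": "g/L",
    "CREA": "umol/L",
    "CRP": "mg/L",
    "WBC": "G/L",
    "BASO_PCT": "%",
    "LYMPH_PCT": "%",
    "NEUT_PCT": "%",
}

_UNIT_ALIASES = {"µmol/L": "umol/L", "μmol/L": "umol/L"}

# letter + 2 digits + up to 2 alphanumerics, dot already stripped
ICD10_RE = re.compile(r"^[A-Z][0-9]{2}[A-Z0-9]{0,2}$")


class RecordsError(Exception):
    """Fatal input error (missing file/column, duplicate roster id, ...)."""


class ConfigError(RecordsError):
    """Invalid or unknown configuration key/value."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Patient:
    patient_id: str
    sex: str  # "male" | "female"
    birth_year: int


@dataclass(frozen=True)
class LabMeasurement:
    patient_id: str
    date: dt.date
    analyte: str
    value: float
    fasting: Optional[bool] = None  # None = unknown


@dataclass(frozen=True)
class DiagnosisEvent:
    patient_id: str
    date: dt.date
    icd10: str


@dataclass
class PatientHistory:
    """One patient's demographics plus date-ordered labs and diagnoses."""

    patient: Patient
    labs: list[LabMeasurement] = field(default_factory=list)
    diagnoses: list[DiagnosisEvent] = field(default_factory=list)


@dataclass
class ReadReport:
    """Per-file accounting: every data row is either accepted or rejected."""

    total_rows: int = 0
    accepted: int = 0
    rejected: int = 0
    reasons: Counter = field(default_factory=Counter)

    def reject(self, reason: str) -> None:
        self.rejected += 1
        self.reasons[reason] += 1


@dataclass
class AssemblyReport:
    orphan_labs: int = 0
    orphan_diagnoses: int = 0


# ---------------------------------------------------------------------------
# criteria configuration

DEFAULT_SECONDARY_FACTOR_CODES: Mapping[str, tuple[str, ...]] = {
    "diabetes": ("E10", "E11", "E12", "E13", "E14"),
    "metabolic_syndrome": ("E8881",),
    "hypothyroidism": ("E03",),
    "corticosteroid_therapy": ("Z795",),
    "alcohol_abuse": ("F10", "Z721"),
}

# prefix "O" covers the whole pregnancy/childbirth chapter O00-O99
DEFAULT_EXEMPTION_CODES: Mapping[str, tuple[str, ...]] = {
    "pregnancy": ("O", "Z32", "Z33", "Z34", "Z35", "Z36", "Z37"),
    "ethinylestradiol": ("Z794",),
}

DEFAULT_PANCREATITIS_CODES: tuple[str, ...] = ("K85", "K860", "K861")
DEFAULT_ABDOMINAL_PAIN_CODES: tuple[str, ...] = ("R10",)
DEFAULT_FCHL_CODES: tuple[str, ...] = ("E782", "Z834")


@dataclass(frozen=True)
class CriteriaConfig:
    """Thresholds and code sets driving the scoring rubric and cascade.

    ``onset_age_bands`` lists ``(exclusive upper age bound, points)`` pairs;
    only the narrowest satisfied band is awarded.
    """

    tg_sustained_threshold: float = 10.0
    tg_sustained_run_length: int = 3
    tg_peak_threshold: float = 20.0
    tg_low_threshold: float = 2.0
    onset_age_bands: tuple[tuple[int, int], ...] = ((10, 3), (20, 2), (40, 1))
    secondary_factor_codes: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SECONDARY_FACTOR_CODES)
    )
    exemption_codes: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_EXEMPTION_CODES)
    )
    pancreatitis_codes: tuple[str, ...] = DEFAULT_PANCREATITIS_CODES
    abdominal_pain_codes: tuple[str, ...] = DEFAULT_ABDOMINAL_PAIN_CODES
    fchl_codes: tuple[str, ...] = DEFAULT_FCHL_CODES
    treatment_response_threshold: float = 0.20
    min_abdominal_pain_events: int = 2
    require_fasting: bool = True
    unknown_fasting_counts_as_fasting: bool = True
    min_tg_records_for_absence_criteria: int = 1
    # alternative category thresholds from the rubric's footnote wording
    footnote_category_thresholds: bool = False

    def __post_init__(self) -> None:
        for name in (
            "tg_sustained_threshold",
            "tg_peak_threshold",
            "tg_low_threshold",
            "treatment_response_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.tg_sustained_run_length < 1:
            raise ConfigError("tg_sustained_run_length must be >= 1")
        bands = tuple(tuple(b) for b in self.onset_age_bands)
        object.__setattr__(self, "onset_age_bands", bands)
        ages = [a for a, _ in bands]
        pts = [p for _, p in bands]
        if ages != sorted(ages) or len(set(ages)) != len(ages):
            raise ConfigError("onset_age_bands ages must be strictly increasing")
        if pts != sorted(pts, reverse=True) or len(set(pts)) != len(pts):
            raise ConfigError("onset_age_bands points must be strictly decreasing")

    def all_secondary_prefixes(self) -> tuple[str, ...]:
        return tuple(p for ps in self.secondary_factor_codes.values() for p in ps)

    def all_exemption_prefixes(self) -> tuple[str, ...]:
        return tuple(p for ps in self.exemption_codes.values() for p in ps)


def matches_any_prefix(code: str, prefixes: Iterable[str]) -> bool:
    return any(code.startswith(p) for p in prefixes)


def load_config(path: Optional[str | Path] = None) -> CriteriaConfig:
    """Load a :class:`CriteriaConfig` from YAML (JSON is valid YAML).

    Unspecified fields take their defaults; unknown keys are fatal.
    """
    if path is None:
        cfg = CriteriaConfig()
    else:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config root must be a mapping")
        known = {f.name for f in fields(CriteriaConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        kwargs = dict(raw)
        for key in ("secondary_factor_codes", "exemption_codes"):
            if key in kwargs:
                kwargs[key] = {k: tuple(v) for k, v in kwargs[key].items()}
        for key in ("pancreatitis_codes", "abdominal_pain_codes", "fchl_codes"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "onset_age_bands" in kwargs:
            kwargs["onset_age_bands"] = tuple(tuple(b) for b in kwargs["onset_age_bands"])
        cfg = CriteriaConfig(**kwargs)
    log.info("effective criteria config: %s", cfg)
    return cfg


# ---------------------------------------------------------------------------
# parsing helpers

_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n"}


def _parse_fasting(text: str) -> Optional[bool]:
    s = text.strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    if s in ("", "unknown", "na", "nan", "none"):
        return None
    raise ValueError(f"unparseable fasting flag {text!r}")


def normalize_icd10(code: str) -> str:
    """Uppercase, strip dots/whitespace, truncate to 5 characters."""
    return code.strip().upper().replace(".", "")[:5]


def _open_reader(path: str | Path, required: Sequence[str], delimiter: str):
    p = Path(path)
    if not p.exists():
        raise RecordsError(f"input file not found: {p}")
    handle = p.open(newline="", encoding="utf-8")
    reader = csv.DictReader(handle, delimiter=delimiter)
    header = reader.fieldnames or []
    for col in required:
        if col not in header:
            handle.close()
            raise RecordsError(f"{p}: missing required column '{col}'")
    return handle, reader


# ---------------------------------------------------------------------------
# readers


def read_lab_records(
    path: str | Path, delimiter: str = ","
) -> tuple[list[LabMeasurement], ReadReport]:
    """Read lab measurements from a long-format CSV.

    Header must name ``patient_id,date,analyte,value``; ``unit`` and
    ``fasting`` are optional. Rows with unparseable values/dates, negative
    values, or a unit conflicting with the analyte's canonical unit are
    dropped and counted in the report.
    """
    handle, reader = _open_reader(path, ("patient_id", "date", "analyte", "value"), delimiter)
    report = ReadReport()
    records: list[LabMeasurement] = []
    with handle:
        for row in reader:
            report.total_rows += 1
            try:
                date = dt.date.fromisoformat(row["date"].strip())
            except (ValueError, AttributeError):
                report.reject("bad_date")
                continue
            try:
                value = float(row["value"])
            except (TypeError, ValueError):
                report.reject("bad_value")
                continue
            if value < 0:
                report.reject("negative_value")
                continue
            analyte = row["analyte"].strip().upper()
            if not analyte:
                report.reject("missing_analyte")
                continue
            unit = (row.get("unit") or "").strip()
            unit = _UNIT_ALIASES.get(unit, unit)
            canonical = CANONICAL_UNITS.get(analyte)
            if unit and canonical is not None and unit != canonical:
                report.reject("unit_mismatch")
                continue
            try:
                fasting = _parse_fasting(row.get("fasting") or "")
            except ValueError:
                report.reject("bad_fasting")
                continue
            records.append(
                LabMeasurement(row["patient_id"].strip(), date, analyte, value, fasting)
            )
            report.accepted += 1
    if report.total_rows == 0:
        log.warning("lab file %s contains no data rows", path)
    if report.rejected:
        log.info("lab file %s: rejected %d/%d rows (%s)", path, report.rejected,
                 report.total_rows, dict(report.reasons))
    return records, report


def read_diagnosis_records(
    path: str | Path, delimiter: str = ","
) -> tuple[list[DiagnosisEvent], ReadReport]:
    """Read diagnosis events; ICD-10 codes are normalized then validated."""
    handle, reader = _open_reader(path, ("patient_id", "date", "icd10"), delimiter)
    report = ReadReport()
    records: list[DiagnosisEvent] = []
    with handle:
        for row in reader:
            report.total_rows += 1
            try:
                date = dt.date.fromisoformat(row["date"].strip())
            except (ValueError, AttributeError):
                report.reject("bad_date")
                continue
            code = normalize_icd10(row["icd10"] or "")
            if not ICD10_RE.match(code):
                report.reject("bad_icd10")
                continue
            records.append(DiagnosisEvent(row["patient_id"].strip(), date, code))
            report.accepted += 1
    if report.rejected:
        log.info("diagnosis file %s: rejected %d/%d rows", path, report.rejected,
                 report.total_rows)
    return records, report


def read_roster(
    path: str | Path, delimiter: str = ","
) -> tuple[list[Patient], ReadReport]:
    """Read the patient roster (``patient_id,sex,birth_year``)."""
    handle, reader = _open_reader(path, ("patient_id", "sex", "birth_year"), delimiter)
    report = ReadReport()
    patients: list[Patient] = []
    this_year = dt.date.today().year
    with handle:
        for row in reader:
            report.total_rows += 1
            sex = (row["sex"] or "").strip().lower()
            if sex not in SEXES:
                report.reject("bad_sex")
                continue
            try:
                birth_year = int(row["birth_year"])
            except (TypeError, ValueError):
                report.reject("bad_birth_year")
                continue
            if not 1900 <= birth_year <= this_year:
                report.reject("birth_year_out_of_range")
                continue
            patients.append(Patient(row["patient_id"].strip(), sex, birth_year))
            report.accepted += 1
    return patients, report


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers)


def write_lab_records(path: str | Path, records: Iterable[LabMeasurement]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "date", "analyte", "value", "unit", "fasting"])
        for r in records:
            fasting = "" if r.fasting is None else str(r.fasting).lower()
            w.writerow(
                [r.patient_id, r.date.isoformat(), r.analyte, repr(r.value),
                 CANONICAL_UNITS.get(r.analyte, ""), fasting]
            )


def write_diagnosis_records(path: str | Path, records: Iterable[DiagnosisEvent]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "date", "icd10"])
        for r in records:
            w.writerow([r.patient_id, r.date.isoformat(), r.icd10])


def write_roster(path: str | Path, patients: Iterable[Patient]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "sex", "birth_year"])
        for p in patients:
            w.writerow([p.patient_id, p.sex, p.birth_year])


# ---------------------------------------------------------------------------
# assembly


def assemble_histories(
    patients: Sequence[Patient],
    labs: Sequence[LabMeasurement],
    diagnoses: Sequence[DiagnosisEvent],
) -> tuple[dict[str, PatientHistory], AssemblyReport]:
    """Group labs/diagnoses per roster patient, date-sorted (stable on ties).

    Every roster patient appears in the result; records for patients missing
    from the roster are excluded and counted as orphans. Duplicate roster
    ids are fatal.
    """
    histories: dict[str, PatientHistory] = {}
    for p in patients:
        if p.patient_id in histories:
            raise RecordsError(f"duplicate patient_id in roster: {p.patient_id}")
        histories[p.patient_id] = PatientHistory(patient=p)
    report = AssemblyReport()
    for lab in labs:
        h = histories.get(lab.patient_id)
        if h is None:
            report.orphan_labs += 1
            continue
        h.labs.append(lab)
    for dx in diagnoses:
        h = histories.get(dx.patient_id)
        if h is None:
            report.orphan_diagnoses += 1
            continue
        h.diagnoses.append(dx)
    for h in histories.values():
        h.labs.sort(key=lambda r: r.date)  # stable: ties keep input order
        h.diagnoses.sort(key=lambda r: r.date)
    if report.orphan_labs or report.orphan_diagnoses:
        log.info("assembly: excluded %d orphan labs, %d orphan diagnoses",
                 report.orphan_labs, report.orphan_diagnoses)
    return histories, report
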