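"""Synthetic longitudinal cohorts with planted ground-truth strata.

Three strata are generated:

* ``FCS`` (rare): sustained fasting TG above 10 mmol/L (first three visits
  guaranteed), never below 2 mmol/L, no secondary-factor codes, onset below
  40 years with about half below 20, pancreatitis with probability 0.5;
* ``MFCS``: high but fluctuating TG (median ~8 mmol/L, occasional dips
  below 2), at least one secondary-factor code, elevated liver
  enzymes/glucose;
* ``background``: normal fasting TG (median 1.3 mmol/L), occasional
  secondary-factor and benign codes.

Lab values are log-normal with per-stratum medians; all parameters live on
:class:`CohortSpec`, not in code. Generation is deterministic per seed.
These distributions are synthetic assumptions (only the cut directions are
anchored to published reference values), not a fit to any real population.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from fcs_screen.records_io import (
    DiagnosisEvent,
    LabMeasurement,
    Patient,
    write_diagnosis_records,
    write_lab_records,
    write_roster,
)

STRATUM_FCS = "FCS"
STRATUM_MFCS = "MFCS"
STRATUM_BACKGROUND = "background"

_CORE_ANALYTES = ("TG", "CHOL")
_PANEL_ANALYTES = ("GLU", "GPT", "GGT", "HGB", "AMYL", "CREA", "NA", "WBC", "CRP", "UREA")

#: (median, log-scale sigma) per analyte, per stratum
_BACKGROUND_LABS: dict[str, tuple[float, float]] = {
    "TG": (1.3, 0.35),
    "CHOL": (5.0, 0.20),
    "GLU": (5.2, 0.15),
    "GPT": (18.0, 0.40),
    "GGT": (28.0, 0.50),
    "HGB": (140.0, 0.08),
    "AMYL": (55.0, 0.30),
    "CREA": (75.0, 0.20),
    "NA": (140.0, 0.02),
    "WBC": (7.0, 0.25),
    "CRP": (3.0, 0.80),
    "UREA": (5.0, 0.30),
}

_MFCS_LABS = dict(
    _BACKGROUND_LABS,
    TG=(8.0, 0.60),
    CHOL=(6.5, 0.20),
    GLU=(7.5, 0.30),
    GPT=(45.0, 0.50),
    GGT=(70.0, 0.50),
)

_FCS_LABS = dict(
    _BACKGROUND_LABS,
    TG=(18.0, 0.50),
    CHOL=(7.0, 0.15),
    GLU=(4.9, 0.12),
    GPT=(14.0, 0.30),
    GGT=(20.0, 0.30),
    HGB=(150.0, 0.07),
    AMYL=(70.0, 0.30),
)

_MFCS_SECONDARY_CODES = ("E1140", "E8881", "E0390", "F1020", "Z795")
_BENIGN_CODES = ("I10", "J069", "M545", "K21", "Z000")


class SpecError(ValueError):
    """Impossible cohort specification."""


@dataclass(frozen=True)
class TruthLabel:
    patient_id: str
    stratum: str


@dataclass
class CohortSpec:
    """Generator parameters; defaults give a small, testable population."""

    n_patients: int = 5000
    fcs_fraction: float = 0.002
    mfcs_fraction: float = 0.01
    seed: int = 0
    visits_mean: float = 8.0
    panel_prob: float = 0.7
    study_start: dt.date = dt.date(2007, 1, 1)
    study_end: dt.date = dt.date(2014, 12, 31)
    # FCS stratum construction
    fcs_min_visits: int = 3
    fcs_tg_floor: float = 2.5
    fcs_tg_guaranteed_high: float = 10.6  # floor for the first run of visits
    fcs_peak_prob: float = 0.9  # chance one visit is forced above the peak cut
    fcs_tg_peak_floor: float = 20.6
    fcs_pancreatitis_prob: float = 0.5
    fcs_abdominal_pain_prob: float = 0.3
    fcs_onset_age_range: tuple[float, float] = (5.0, 40.0)
    fcs_young_fraction: float = 0.5  # fraction with onset below 20
    fcs_male_fraction: float = 0.8
    fcs_chol_range: tuple[float, float] = (4.2, 10.8)
    # MFCS stratum
    mfcs_dip_prob: float = 0.3  # at least one TG below 2 mmol/L
    mfcs_pancreatitis_prob: float = 0.15
    mfcs_abdominal_pain_prob: float = 0.2
    mfcs_onset_age_range: tuple[float, float] = (30.0, 70.0)
    # background stratum
    background_secondary_prob: float = 0.15
    background_pancreatitis_prob: float = 0.003
    background_age_range: tuple[float, float] = (5.0, 85.0)
    male_fraction: float = 0.45
    lab_params: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            STRATUM_BACKGROUND: dict(_BACKGROUND_LABS),
            STRATUM_MFCS: dict(_MFCS_LABS),
            STRATUM_FCS: dict(_FCS_LABS),
        }
    )

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise SpecError("n_patients must be >= 1")
        for name in ("fcs_fraction", "mfcs_fraction"):
            frac = getattr(self, name)
            if not 0.0 <= frac <= 1.0:
                raise SpecError(f"{name} must be in [0, 1]")
        if self.fcs_fraction + self.mfcs_fraction > 1.0:
            raise SpecError("stratum fractions must sum to at most 1")


def planted_score_floor(spec: CohortSpec) -> int:
    """Guaranteed minimum rubric total for the planted FCS stratum.

    Deterministic criteria: sustained TG (+5), no secondary factor (+2) and
    the onset-age band implied by the spec's maximum onset age. Pancreatitis
    contributes only when its probability is 1. The peak-TG, abdominal-pain
    and narrower onset bands remain stochastic and are excluded; the no-FCHL
    criterion, though satisfied by construction, is likewise not counted.
    """
    floor = 5 + 2
    onset_max = spec.fcs_onset_age_range[1]
    if onset_max <= 10:
        floor += 3
    elif onset_max <= 20:
        floor += 2
    elif onset_max <= 40:
        floor += 1
    if spec.fcs_pancreatitis_prob >= 1.0:
        floor += 1
    if spec.fcs_peak_prob >= 1.0:
        floor += 1
    return floor


def _lognormal(rng: np.random.Generator, median: float, sigma: float) -> float:
    return float(median * np.exp(sigma * rng.standard_normal()))


def _draw_onset_age(rng: np.random.Generator, spec: CohortSpec, stratum: str) -> float:
    if stratum == STRATUM_FCS:
        lo, hi = spec.fcs_onset_age_range
        young_hi = min(20.0, hi)
        if hi > 20.0 and rng.random() >= spec.fcs_young_fraction:
            return float(rng.uniform(young_hi, hi))
        return float(rng.uniform(lo, young_hi))
    if stratum == STRATUM_MFCS:
        lo, hi = spec.mfcs_onset_age_range
    else:
        lo, hi = spec.background_age_range
    return float(rng.uniform(lo, hi))


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[Patient], list[LabMeasurement], list[DiagnosisEvent], list[TruthLabel]]:
    """Generate (roster, labs, diagnoses, truth labels) for one cohort."""
    rng = np.random.default_rng(spec.seed)
    n_days = (spec.study_end - spec.study_start).days + 1
    roster: list[Patient] = []
    labs: list[LabMeasurement] = []
    diagnoses: list[DiagnosisEvent] = []
    truth: list[TruthLabel] = []

    for i in range(spec.n_patients):
        pid = f"P{i:06d}"
        u = rng.random()
        if u < spec.fcs_fraction:
            stratum = STRATUM_FCS
        elif u < spec.fcs_fraction + spec.mfcs_fraction:
            stratum = STRATUM_MFCS
        else:
            stratum = STRATUM_BACKGROUND
        truth.append(TruthLabel(pid, stratum))

        male_frac = spec.fcs_male_fraction if stratum == STRATUM_FCS else spec.male_fraction
        sex = "male" if rng.random() < male_frac else "female"

        min_visits = spec.fcs_min_visits if stratum == STRATUM_FCS else 1
        n_visits = max(min_visits, int(rng.poisson(spec.visits_mean)))
        day_offsets = np.sort(rng.choice(n_days, size=n_visits, replace=False))
        visit_dates = [spec.study_start + dt.timedelta(days=int(d)) for d in day_offsets]

        onset_age = _draw_onset_age(rng, spec, stratum)
        birth_year = max(1901, visit_dates[0].year - int(onset_age))
        roster.append(Patient(pid, sex, birth_year))

        params = spec.lab_params[stratum]

        # per-visit fasting status; early FCS visits forced fasting so the
        # sustained-TG run is guaranteed
        fasting_flags: list[bool | None] = []
        for v in range(n_visits):
            if stratum == STRATUM_FCS and v < spec.fcs_min_visits:
                fasting_flags.append(True)
            else:
                f = rng.random()
                fasting_flags.append(True if f < 0.85 else (None if f < 0.95 else False))

        tg_values = []
        for v in range(n_visits):
            median, sigma = params["TG"]
            tg = _lognormal(rng, median, sigma)
            if stratum == STRATUM_FCS:
                tg = max(tg, spec.fcs_tg_floor)
                if v < spec.fcs_min_visits:
                    tg = max(tg, spec.fcs_tg_guaranteed_high)
            tg_values.append(round(tg, 2))
        if stratum == STRATUM_FCS and rng.random() < spec.fcs_peak_prob:
            peak_at = int(rng.integers(n_visits))
            tg_values[peak_at] = round(max(tg_values[peak_at], spec.fcs_tg_peak_floor), 2)
            fasting_flags[peak_at] = True  # the peak must be fasting-eligible
        if stratum == STRATUM_MFCS and rng.random() < spec.mfcs_dip_prob:
            dip_at = int(rng.integers(n_visits))
            tg_values[dip_at] = round(float(rng.uniform(0.8, 1.9)), 2)

        for v, date in enumerate(visit_dates):
            fasting = fasting_flags[v]
            labs.append(LabMeasurement(pid, date, "TG", tg_values[v], fasting))
            if stratum == STRATUM_FCS:
                lo, hi = spec.fcs_chol_range
                chol = float(np.clip(_lognormal(rng, *params["CHOL"]), lo, hi))
            else:
                chol = _lognormal(rng, *params["CHOL"])
            labs.append(LabMeasurement(pid, date, "CHOL", round(chol, 2), fasting))
            for analyte in _PANEL_ANALYTES:
                if rng.random() < spec.panel_prob:
                    value = _lognormal(rng, *params[analyte])
                    labs.append(LabMeasurement(pid, date, analyte, round(value, 2), fasting))

        def _random_visit_date() -> dt.date:
            return visit_dates[int(rng.integers(n_visits))]

        if stratum == STRATUM_FCS:
            if rng.random() < spec.fcs_pancreatitis_prob:
                diagnoses.append(DiagnosisEvent(pid, _random_visit_date(), "K850"))
            if n_visits >= 2 and rng.random() < spec.fcs_abdominal_pain_prob:
                picks = rng.choice(n_visits, size=2, replace=False)
                for v in picks:
                    diagnoses.append(DiagnosisEvent(pid, visit_dates[int(v)], "R100"))
        elif stratum == STRATUM_MFCS:
            n_codes = int(rng.integers(1, 4))
            picks = rng.choice(len(_MFCS_SECONDARY_CODES), size=n_codes, replace=False)
            for c in picks:
                diagnoses.append(
                    DiagnosisEvent(pid, _random_visit_date(), _MFCS_SECONDARY_CODES[int(c)])
                )
            if rng.random() < spec.mfcs_pancreatitis_prob:
                diagnoses.append(DiagnosisEvent(pid, _random_visit_date(), "K850"))
            if n_visits >= 2 and rng.random() < spec.mfcs_abdominal_pain_prob:
                picks = rng.choice(n_visits, size=2, replace=False)
                for v in picks:
                    diagnoses.append(DiagnosisEvent(pid, visit_dates[int(v)], "R100"))
        else:
            if rng.random() < spec.background_secondary_prob:
                code = _MFCS_SECONDARY_CODES[int(rng.integers(len(_MFCS_SECONDARY_CODES)))]
                diagnoses.append(DiagnosisEvent(pid, _random_visit_date(), code))
            n_benign = int(rng.integers(0, 3))
            for _ in range(n_benign):
                code = _BENIGN_CODES[int(rng.integers(len(_BENIGN_CODES)))]
                diagnoses.append(DiagnosisEvent(pid, _random_visit_date(), code))
            if rng.random() < spec.background_pancreatitis_prob:
                diagnoses.append(DiagnosisEvent(pid, _random_visit_date(), "K850"))
            if sex == "female" and rng.random() < 0.05:
                diagnoses.append(DiagnosisEvent(pid, _random_visit_date(), "O800"))

    return roster, labs, diagnoses, truth


def write_cohort(
    out_dir: str | Path,
    roster: list[Patient],
    labs: list[LabMeasurement],
    diagnoses: list[DiagnosisEvent],
    truth: list[TruthLabel],
) -> None:
    """Write the four cohort CSVs (labs, diagnoses, roster, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_lab_records(out / "labs.csv", labs)
    write_diagnosis_records(out / "diagnoses.csv", diagnoses)
    write_roster(out / "roster.csv", roster)
    with (out / "truth.csv").open("w", encoding="utf-8") as fh:
        fh.write("patient_id,stratum\n")
        for t in truth:
            fh.write(f"{t.patient_id},{t.stratum}\n")


def read_truth(path: str | Path) -> list[TruthLabel]:
    labels = []
    with Path(path).open(encoding="utf-8") as fh:
        header = fh.readline()
        if header.strip() != "patient_id,stratum":
            raise ValueError("truth file must have header 'patient_id,stratum'")
        for line in fh:
            pid, stratum = line.strip().split(",")
            labels.append(TruthLabel(pid, stratum))
    return labels
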