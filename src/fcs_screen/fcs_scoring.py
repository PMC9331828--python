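"""Rule-based FCS score: per-criterion points, total and category.

Criterion semantics (all thresholds strict inequalities):

* sustained: +5 for a run of ``tg_sustained_run_length`` consecutive entries,
  within the date-ordered sequence of fasting-eligible TG measurements, each
  above ``tg_sustained_threshold``;
* peak: +1 for any fasting-eligible TG above ``tg_peak_threshold``;
* prior low: -5 for any TG (fasting or not) below ``tg_low_threshold``;
* no secondary factor: +2, gated (see below), ignoring exempt codes
  (pregnancy, ethinylestradiol);
* pancreatitis: +1; recurrent abdominal pain (>= 2 distinct dates): +1;
* no familial-combined-hyperlipidemia history: +1, gated;
* treatment non-response (< 20 % median TG decrease): +1 when a treatment
  start date is supplied;
* symptom onset age: narrowest band only (< 10: +3, < 20: +2, < 40: +1),
  onset proxied by the earliest of first high TG and first pancreatitis.

The absence-based criteria (+2 no secondary factor, +1 no FCHL) only apply
to patients with at least one TG above the sustained threshold; ungated,
every record-poor patient would collect +3 vacuously.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from statistics import median
from typing import Optional

from fcs_screen.records_io import (
    CriteriaConfig,
    LabMeasurement,
    PatientHistory,
    matches_any_prefix,
)

CATEGORY_LIKELY = "likely"
CATEGORY_UNLIKELY = "unlikely"
CATEGORY_HIGHLY_UNLIKELY = "highly_unlikely"

SCORE_MIN = -5
SCORE_MAX = 15


@dataclass(frozen=True)
class FCSScoreResult:
    patient_id: str
    points_sustained_tg: int
    points_peak_tg: int
    points_prior_low_tg: int
    points_no_secondary: int
    points_pancreatitis: int
    points_abdominal_pain: int
    points_no_fchl: int
    points_nonresponse: int
    points_onset_age: int
    total: int
    evaluable: bool
    category: str

    @property
    def breakdown_sum(self) -> int:
        return (
            self.points_sustained_tg
            + self.points_peak_tg
            + self.points_prior_low_tg
            + self.points_no_secondary
            + self.points_pancreatitis
            + self.points_abdominal_pain
            + self.points_no_fchl
            + self.points_nonresponse
            + self.points_onset_age
        )


# ---------------------------------------------------------------------------
# shared predicates (single source of truth for scoring and the cascade)


def fasting_eligible_tg(history: PatientHistory, cfg: CriteriaConfig) -> list[LabMeasurement]:
    """Date-ordered TG measurements usable for the fasting criteria."""
    out = []
    for lab in history.labs:
        if lab.analyte != "TG":
            continue
        if cfg.require_fasting:
            if lab.fasting is False:
                continue
            if lab.fasting is None and not cfg.unknown_fasting_counts_as_fasting:
                continue
        out.append(lab)
    return out


def all_tg(history: PatientHistory) -> list[LabMeasurement]:
    return [lab for lab in history.labs if lab.analyte == "TG"]


def has_sustained_tg(history: PatientHistory, cfg: CriteriaConfig) -> bool:
    run = 0
    for lab in fasting_eligible_tg(history, cfg):
        run = run + 1 if lab.value > cfg.tg_sustained_threshold else 0
        if run >= cfg.tg_sustained_run_length:
            return True
    return False


def has_peak_tg(history: PatientHistory, cfg: CriteriaConfig) -> bool:
    return any(l.value > cfg.tg_peak_threshold for l in fasting_eligible_tg(history, cfg))


def has_low_tg(history: PatientHistory, cfg: CriteriaConfig) -> bool:
    return any(l.value < cfg.tg_low_threshold for l in all_tg(history))


def absence_gate(history: PatientHistory, cfg: CriteriaConfig) -> bool:
    """Evaluability gate for the absence-based criteria."""
    n = sum(
        1
        for l in fasting_eligible_tg(history, cfg)
        if l.value > cfg.tg_sustained_threshold
    )
    return n >= cfg.min_tg_records_for_absence_criteria


def has_secondary_factor(history: PatientHistory, cfg: CriteriaConfig) -> bool:
    secondary = cfg.all_secondary_prefixes()
    exempt = cfg.all_exemption_prefixes()
    for dx in history.diagnoses:
        if matches_any_prefix(dx.icd10, exempt):
            continue
        if matches_any_prefix(dx.icd10, secondary):
            return True
    return False


def has_pancreatitis(history: PatientHistory, cfg: CriteriaConfig) -> bool:
    return any(matches_any_prefix(d.icd10, cfg.pancreatitis_codes) for d in history.diagnoses)


def has_fchl(history: PatientHistory, cfg: CriteriaConfig) -> bool:
    return any(matches_any_prefix(d.icd10, cfg.fchl_codes) for d in history.diagnoses)


def onset_age(history: PatientHistory, cfg: CriteriaConfig) -> Optional[int]:
    """Age in whole years at the onset proxy, or None if no qualifying event.

    Onset = earliest of (first fasting-eligible TG above the sustained
    threshold, first pancreatitis diagnosis). Age uses calendar years.
    """
    dates: list[dt.date] = []
    for lab in fasting_eligible_tg(history, cfg):
        if lab.value > cfg.tg_sustained_threshold:
            dates.append(lab.date)
            break
    for dx in history.diagnoses:
        if matches_any_prefix(dx.icd10, cfg.pancreatitis_codes):
            dates.append(dx.date)
            break
    if not dates:
        return None
    return min(dates).year - history.patient.birth_year


# ---------------------------------------------------------------------------
# criterion operations


def tg_criteria_points(
    history: PatientHistory, cfg: CriteriaConfig
) -> tuple[int, int, int]:
    """(sustained in {0,5}, peak in {0,1}, prior_low in {0,-5})."""
    sustained = 5 if has_sustained_tg(history, cfg) else 0
    peak = 1 if has_peak_tg(history, cfg) else 0
    prior_low = -5 if has_low_tg(history, cfg) else 0
    return sustained, peak, prior_low


def secondary_factor_points(history: PatientHistory, cfg: CriteriaConfig) -> int:
    if not absence_gate(history, cfg):
        return 0
    return 0 if has_secondary_factor(history, cfg) else 2


def event_criteria_points(
    history: PatientHistory, cfg: CriteriaConfig
) -> tuple[int, int, int]:
    """(pancreatitis in {0,1}, abdominal_pain in {0,1}, no_fchl in {0,1})."""
    pancreatitis = 1 if has_pancreatitis(history, cfg) else 0
    pain_dates = {
        d.date
        for d in history.diagnoses
        if matches_any_prefix(d.icd10, cfg.abdominal_pain_codes)
    }
    abdominal_pain = 1 if len(pain_dates) >= cfg.min_abdominal_pain_events else 0
    no_fchl = 1 if absence_gate(history, cfg) and not has_fchl(history, cfg) else 0
    return pancreatitis, abdominal_pain, no_fchl


def treatment_nonresponse_points(
    history: PatientHistory,
    cfg: CriteriaConfig,
    treatment_start: Optional[dt.date] = None,
) -> int:
    """+1 when median TG drops by less than the response threshold."""
    if treatment_start is None:
        return 0
    before = [l.value for l in all_tg(history) if l.date < treatment_start]
    after = [l.value for l in all_tg(history) if l.date >= treatment_start]
    if not before or not after:
        return 0
    m_before, m_after = median(before), median(after)
    if m_before <= 0:
        return 0
    decrease = (m_before - m_after) / m_before
    return 1 if decrease < cfg.treatment_response_threshold else 0


def onset_age_points(history: PatientHistory, cfg: CriteriaConfig) -> int:
    age = onset_age(history, cfg)
    if age is None:
        return 0
    for bound, points in cfg.onset_age_bands:  # bands ascend; first hit is narrowest
        if age < bound:
            return points
    return 0


def classify_score(total: int, cfg: Optional[CriteriaConfig] = None) -> str:
    """Map a total score to a category.

    Default clustering: >= 10 likely, 8-9 unlikely, <= 7 highly unlikely.
    With ``footnote_category_thresholds``: > 10 likely, 9-10 unlikely.
    """
    if cfg is not None and cfg.footnote_category_thresholds:
        if total > 10:
            return CATEGORY_LIKELY
        if total >= 9:
            return CATEGORY_UNLIKELY
        return CATEGORY_HIGHLY_UNLIKELY
    if total >= 10:
        return CATEGORY_LIKELY
    if total >= 8:
        return CATEGORY_UNLIKELY
    return CATEGORY_HIGHLY_UNLIKELY


def compute_fcs_score(
    history: PatientHistory,
    cfg: CriteriaConfig,
    treatment_start: Optional[dt.date] = None,
) -> FCSScoreResult:
    """Evaluate the full rubric for one patient history."""
    sustained, peak, prior_low = tg_criteria_points(history, cfg)
    no_secondary = secondary_factor_points(history, cfg)
    pancreatitis, abdominal_pain, no_fchl = event_criteria_points(history, cfg)
    nonresponse = treatment_nonresponse_points(history, cfg, treatment_start)
    onset = onset_age_points(history, cfg)
    total = (
        sustained + peak + prior_low + no_secondary + pancreatitis
        + abdominal_pain + no_fchl + nonresponse + onset
    )
    return FCSScoreResult(
        patient_id=history.patient.patient_id,
        points_sustained_tg=sustained,
        points_peak_tg=peak,
        points_prior_low_tg=prior_low,
        points_no_secondary=no_secondary,
        points_pancreatitis=pancreatitis,
        points_abdominal_pain=abdominal_pain,
        points_no_fchl=no_fchl,
        points_nonresponse=nonresponse,
        points_onset_age=onset,
        total=total,
        evaluable=absence_gate(history, cfg),
        category=classify_score(total, cfg),
    )
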