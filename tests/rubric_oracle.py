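"""Independent brute-force evaluator of the scoring rubric.

Written directly from the published point table and the documented
operationalizations, deliberately sharing no code with the package's
scoring engine: every criterion is evaluated by explicit enumeration over
the raw record lists.
"""

import datetime as dt
from statistics import median


def _eligible_tg(history, cfg):
    seq = []
    for lab in history.labs:
        if lab.analyte != "TG":
            continue
        if cfg.require_fasting and lab.fasting is False:
            continue
        if (
            cfg.require_fasting
            and lab.fasting is None
            and not cfg.unknown_fasting_counts_as_fasting
        ):
            continue
        seq.append(lab)
    return seq


def _code_in(code, prefix_sets):
    for prefixes in prefix_sets:
        for prefix in prefixes:
            if code.startswith(prefix):
                return True
    return False


def oracle_score(history, cfg, treatment_start=None):
    """Return (breakdown dict, total, category) for one history."""
    eligible = _eligible_tg(history, cfg)
    every_tg = [l for l in history.labs if l.analyte == "TG"]
    run_len = cfg.tg_sustained_run_length

    # +5: some window of `run_len` consecutive eligible analyses all high
    sustained = 0
    for start in range(len(eligible) - run_len + 1):
        window = eligible[start : start + run_len]
        if all(l.value > cfg.tg_sustained_threshold for l in window):
            sustained = 5
            break

    peak = 1 if any(l.value > cfg.tg_peak_threshold for l in eligible) else 0
    prior_low = -5 if any(l.value < cfg.tg_low_threshold for l in every_tg) else 0

    n_high = len([l for l in eligible if l.value > cfg.tg_sustained_threshold])
    gate = n_high >= cfg.min_tg_records_for_absence_criteria

    secondary_sets = list(cfg.secondary_factor_codes.values())
    exemption_sets = list(cfg.exemption_codes.values())
    secondary_present = False
    for dx in history.diagnoses:
        if _code_in(dx.icd10, exemption_sets):
            continue
        if _code_in(dx.icd10, secondary_sets):
            secondary_present = True
    no_secondary = 2 if gate and not secondary_present else 0

    pancreatitis = 0
    panc_dates = []
    for dx in history.diagnoses:
        if _code_in(dx.icd10, [cfg.pancreatitis_codes]):
            pancreatitis = 1
            panc_dates.append(dx.date)

    pain_dates = set()
    for dx in history.diagnoses:
        if _code_in(dx.icd10, [cfg.abdominal_pain_codes]):
            pain_dates.add(dx.date)
    abdominal_pain = 1 if len(pain_dates) >= cfg.min_abdominal_pain_events else 0

    fchl_present = any(
        _code_in(dx.icd10, [cfg.fchl_codes]) for dx in history.diagnoses
    )
    no_fchl = 1 if gate and not fchl_present else 0

    nonresponse = 0
    if treatment_start is not None:
        before = [l.value for l in every_tg if l.date < treatment_start]
        after = [l.value for l in every_tg if l.date >= treatment_start]
        if before and after and median(before) > 0:
            drop = (median(before) - median(after)) / median(before)
            if drop < cfg.treatment_response_threshold:
                nonresponse = 1

    onset_dates = []
    for lab in eligible:
        if lab.value > cfg.tg_sustained_threshold:
            onset_dates.append(lab.date)
            break
    if panc_dates:
        onset_dates.append(min(panc_dates))
    onset = 0
    if onset_dates:
        age = min(onset_dates).year - history.patient.birth_year
        for bound, points in sorted(cfg.onset_age_bands):
            if age < bound:
                onset = points
                break

    breakdown = {
        "sustained": sustained,
        "peak": peak,
        "prior_low": prior_low,
        "no_secondary": no_secondary,
        "pancreatitis": pancreatitis,
        "abdominal_pain": abdominal_pain,
        "no_fchl": no_fchl,
        "nonresponse": nonresponse,
        "onset": onset,
    }
    total = sum(breakdown.values())
    if total >= 10:
        category = "likely"
    elif total >= 8:
        category = "unlikely"
    else:
        category = "highly_unlikely"
    return breakdown, total, category


def oracle_auc(scores, labels):
    """Exhaustive pair-counting AUC with ties worth 1/2."""
    pairs = 0
    wins = 0.0
    for s_pos, l_pos in zip(scores, labels):
        if l_pos != 1:
            continue
        for s_neg, l_neg in zip(scores, labels):
            if l_neg != 0:
                continue
            pairs += 1
            if s_pos > s_neg:
                wins += 1.0
            elif s_pos == s_neg:
                wins += 0.5
    if pairs == 0:
        raise ValueError("both classes required")
    return wins / pairs
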