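"""Rapid score estimation: sequential population filters with running
score attribution.

The cascade reuses the scoring module's predicates, so its survivors are by
construction a subset of patients whose full score reaches each stage's
label (the cascade's conditions exclude the -5 criterion and omit the
abdominal-pain, FCHL and treatment criteria).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from fcs_screen.cohort_statistics import RateValue, auto_scale, format_rate, prevalence_rate
from fcs_screen.fcs_scoring import (
    has_low_tg,
    has_pancreatitis,
    has_peak_tg,
    has_secondary_factor,
    has_sustained_tg,
    onset_age,
)
from fcs_screen.records_io import CriteriaConfig, PatientHistory


@dataclass(frozen=True)
class CascadeStage:
    name: str
    score_label: str
    count: int
    rate: RateValue


@dataclass(frozen=True)
class CascadeResult:
    stages: tuple[CascadeStage, ...]
    population: int


def _stage_predicates(cfg: CriteriaConfig):
    max_onset = max(bound for bound, _ in cfg.onset_age_bands)

    def onset_young(h: PatientHistory) -> bool:
        age = onset_age(h, cfg)
        return age is not None and age < max_onset

    return (
        ("all_patients", "0+", lambda h: True),
        (
            "sustained_tg_never_low",
            "5+",
            lambda h: has_sustained_tg(h, cfg) and not has_low_tg(h, cfg),
        ),
        ("no_secondary_factor", "7+", lambda h: not has_secondary_factor(h, cfg)),
        ("peak_tg", "8+", lambda h: has_peak_tg(h, cfg)),
        ("onset_before_40", "9+", onset_young),
        ("pancreatitis", "10+", lambda h: has_pancreatitis(h, cfg)),
    )


def run_cascade(
    histories: Mapping[str, PatientHistory], cfg: CriteriaConfig
) -> CascadeResult:
    """Apply the six cascade stages, reporting survivors and rates."""
    population = len(histories)
    survivors = list(histories.values())
    stages = []
    for name, label, predicate in _stage_predicates(cfg):
        survivors = [h for h in survivors if predicate(h)]
        n = len(survivors)
        rate = prevalence_rate(n, population, auto_scale(n, population)) if population else RateValue(0.0, auto_scale(1, 1))
        stages.append(CascadeStage(name, label, n, rate))
    return CascadeResult(tuple(stages), population)


def cascade_frame(result: CascadeResult) -> pd.DataFrame:
    """Stage table (feature, score label, count, formatted rate)."""
    return pd.DataFrame(
        {
            "feature": [s.name for s in result.stages],
            "score": [s.score_label for s in result.stages],
            "patients": [s.count for s in result.stages],
            "rate": [format_rate(s.rate) for s in result.stages],
        }
    )
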