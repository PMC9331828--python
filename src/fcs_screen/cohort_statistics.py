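"""Prevalence rates with mixed scale units and score-distribution tables.

Rates are printed at a scale chosen so the value stays readable: percent,
per mille, per ten thousand, per 100,000 (pcm) or per million (ppm), with
half-up rounding at two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Optional, Sequence

import pandas as pd

from fcs_screen.fcs_scoring import FCSScoreResult
from fcs_screen.records_io import Patient


class Scale(Enum):
    """Rate scale: multiplier and printed suffix."""

    percent = (100, "%")
    permille = (1_000, "‰")
    per_ten_thousand = (10_000, "‱")
    pcm = (100_000, " pcm")
    ppm = (1_000_000, " ppm")

    @property
    def factor(self) -> int:
        return self.value[0]

    @property
    def suffix(self) -> str:
        return self.value[1]


@dataclass(frozen=True)
class RateValue:
    value: float
    scale: Scale
    decimals: int = 2


@dataclass(frozen=True)
class DistributionRow:
    threshold: int
    male_count: int
    female_count: int
    total_count: int
    male_pct: float
    female_pct: float
    rate: RateValue


def prevalence_rate(
    count: int, population: int, scale: Scale, decimals: int = 2
) -> RateValue:
    """``count / population`` at the given scale, rounded half-up."""
    if population <= 0:
        raise ValueError("population must be positive")
    if not 0 <= count <= population:
        raise ValueError("count must be within [0, population]")
    exact = Decimal(count) * scale.factor / Decimal(population)
    quantum = Decimal(1).scaleb(-decimals)
    value = float(exact.quantize(quantum, rounding=ROUND_HALF_UP))
    return RateValue(value, scale, decimals)


def auto_scale(count: int, population: int) -> Scale:
    """Smallest scale whose value reaches 1 (falls back to ppm)."""
    for scale in Scale:
        if count * scale.factor >= population:
            return scale
    return Scale.ppm


def format_rate(rate: RateValue) -> str:
    return f"{rate.value:.{rate.decimals}f}{rate.scale.suffix}"


def score_distribution(
    results: Sequence[FCSScoreResult],
    roster: Sequence[Patient],
    cumulative: bool = True,
) -> list[DistributionRow]:
    """Score-threshold table with sex split and auto-scaled rates.

    Totals are floored at 0 (the 0+ row covers the whole roster). With
    ``cumulative`` (default) row ``k`` counts patients scoring >= k;
    otherwise rows are disjoint bins (== k).
    """
    sex_by_id = {p.patient_id: p.sex for p in roster}
    seen = set()
    totals: list[tuple[int, str]] = []
    for r in results:
        sex = sex_by_id.get(r.patient_id)
        if sex is None:
            raise ValueError(f"score result for unknown patient {r.patient_id}")
        if r.patient_id in seen:
            raise ValueError(f"duplicate score result for patient {r.patient_id}")
        seen.add(r.patient_id)
        totals.append((max(r.total, 0), sex))
    population = len(roster)
    max_total = max((t for t, _ in totals), default=0)
    rows = []
    for k in range(0, max_total + 1):
        if cumulative:
            bucket = [(t, s) for t, s in totals if t >= k]
        else:
            bucket = [(t, s) for t, s in totals if t == k]
        male = sum(1 for _, s in bucket if s == "male")
        female = len(bucket) - male
        n = len(bucket)
        male_pct = 100.0 * male / n if n else 0.0
        female_pct = 100.0 * female / n if n else 0.0
        rate = prevalence_rate(n, population, auto_scale(n, population))
        rows.append(DistributionRow(k, male, female, n, male_pct, female_pct, rate))
    return rows


def distribution_frame(rows: Iterable[DistributionRow]) -> pd.DataFrame:
    """Tabular form of a score distribution for CSV export."""
    return pd.DataFrame(
        {
            "score": [f"{r.threshold}+" for r in rows],
            "male": [r.male_count for r in rows],
            "female": [r.female_count for r in rows],
            "total": [r.total_count for r in rows],
            "male_pct": [round(r.male_pct, 1) for r in rows],
            "female_pct": [round(r.female_pct, 1) for r in rows],
            "rate": [format_rate(r.rate) for r in rows],
        }
    )
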