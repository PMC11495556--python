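"""Clinical-characteristics summary of the target-drug case cohort.

Gender, age bins, reporter type, top reporting countries, reporting year
and a single (highest-precedence) serious outcome per case, each with
counts and two-decimal percentages of the cohort total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .faers_io import ParseLog
from .preprocess import AnalysisCase

__all__ = [
    "AGE_BIN_LABELS",
    "DEFAULT_OUTCOME_PRECEDENCE",
    "OUTCOME_LABELS",
    "REPORTER_LABELS",
    "CharacteristicsTable",
    "assign_primary_outcome",
    "bin_age",
    "summarize_characteristics",
]

AGE_BIN_LABELS = ("<18", "18~64", "65~85", ">85", "Unknown")

OUTCOME_LABELS: Mapping[str, str] = {
    "DE": "Death",
    "LT": "Life-Threatening",
    "HO": "Hospitalization (initial or prolonged)",
    "DS": "Disability",
    "CA": "Congenital Anomaly",
    "RI": "Required Intervention to Prevent Permanent",
    "OT": "Other Serious (Important Medical Event)",
}

#: Death first; severity-ordered collapse of multi-outcome cases.
DEFAULT_OUTCOME_PRECEDENCE = ("DE", "LT", "DS", "CA", "RI", "HO", "OT")

#: occp_cod -> display label; OT (other health professional) folds into
#: the Health Professional row.
REPORTER_LABELS: Mapping[str, str] = {
    "CN": "Consumer",
    "HP": "Health Professional",
    "OT": "Health Professional",
    "MD": "Physician",
    "PH": "Pharmacist",
}

SEX_LABELS = {"M": "Male", "F": "Female", "UNK": "Unknown"}


def bin_age(age_years: float | None, log: ParseLog | None = None) -> str:
    """Bin an age in years into <18 / 18~64 / 65~85 / >85 / Unknown.

    The age is rounded to the nearest whole year first, so 64.6 lands in
    65~85 and 85 is included in 65~85 (closed upper bound).
    """
    if age_years is None or (isinstance(age_years, float) and math.isnan(age_years)):
        return "Unknown"
    if age_years < 0:
        if log is not None:
            log.warn("negative_age", f"{age_years}")
        return "Unknown"
    age = int(math.floor(age_years + 0.5))
    if age < 18:
        return "<18"
    if age <= 64:
        return "18~64"
    if age <= 85:
        return "65~85"
    return ">85"


def assign_primary_outcome(
    outcomes: Iterable[str],
    precedence: Sequence[str] = DEFAULT_OUTCOME_PRECEDENCE,
    log: ParseLog | None = None,
) -> str:
    """Collapse a case's outcome codes to one label by precedence order."""
    codes = {c for c in outcomes}
    unknown = codes - set(OUTCOME_LABELS)
    if unknown and log is not None:
        log.warn("unknown_outcome", ",".join(sorted(unknown)))
    codes &= set(OUTCOME_LABELS)
    for code in precedence:
        if code in codes:
            return OUTCOME_LABELS[code]
    return "Unknown"


@dataclass
class CharacteristicsTable:
    rows: list[tuple[str, str, int, float]]  # (category, level, count, percent)
    total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["category", "level", "count", "percent"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def percent_of(self, category: str, level: str) -> float:
        for cat, lev, _, pct in self.rows:
            if cat == category and lev == level:
                return pct
        raise KeyError((category, level))

    def count_of(self, category: str, level: str) -> int:
        for cat, lev, count, _ in self.rows:
            if cat == category and lev == level:
                return count
        raise KeyError((category, level))


def _pct(count: int, total: int) -> float:
    return round(100.0 * count / total, 2)


def summarize_characteristics(
    cases: Sequence[AnalysisCase],
    top_n_countries: int = 5,
    outcome_precedence: Sequence[str] = DEFAULT_OUTCOME_PRECEDENCE,
    reporter_labels: Mapping[str, str] = REPORTER_LABELS,
    log: ParseLog | None = None,
) -> CharacteristicsTable:
    """Build the per-category count/percent table for a case cohort.

    Every category except the top-N country block sums to the cohort size;
    Unknown levels absorb missing values.
    """
    if not cases:
        raise ValueError("empty case cohort")
    total = len(cases)
    rows: list[tuple[str, str, int, float]] = []

    def emit(category: str, counter: Counter, order: Sequence[str] | None = None) -> None:
        levels = list(order) if order is not None else [
            lev for lev, _ in counter.most_common()
        ]
        for level in levels:
            count = counter.get(level, 0)
            if count == 0 and order is None:
                continue
            rows.append((category, level, count, _pct(count, total)))

    sex_counts = Counter(SEX_LABELS.get(c.sex, "Unknown") for c in cases)
    emit("Gender", sex_counts, ("Female", "Male", "Unknown"))

    age_counts = Counter(bin_age(c.age_years, log) for c in cases)
    emit("Age (year)", age_counts, AGE_BIN_LABELS)

    rep_counts = Counter(
        reporter_labels.get(c.occp_cod or "", "Unknown") for c in cases
    )
    rep_order = [*dict.fromkeys(reporter_labels.values()), "Unknown"]
    emit("Reported person", rep_counts, rep_order)

    country_counts = Counter(c.country for c in cases if c.country)
    top = country_counts.most_common(top_n_countries)
    for country, count in top:
        rows.append((f"Reported countries (top {top_n_countries})", country, count,
                     _pct(count, total)))

    year_counts = Counter(
        str(c.report_year) if c.report_year is not None else "Unknown" for c in cases
    )
    year_order = sorted(k for k in year_counts if k != "Unknown")
    if "Unknown" in year_counts:
        year_order.append("Unknown")
    emit("Reporting year", year_counts, year_order)

    outcome_counts = Counter(
        assign_primary_outcome(c.outcomes, outcome_precedence, log) for c in cases
    )
    outcome_order = [OUTCOME_LABELS[c] for c in outcome_precedence] + ["Unknown"]
    # present in descending count like the published layout, Unknown last
    outcome_order = sorted(
        outcome_order, key=lambda lev: (lev == "Unknown", -outcome_counts.get(lev, 0))
    )
    emit("Serious outcome", outcome_counts,
         [lev for lev in outcome_order if outcome_counts.get(lev, 0) or lev == "Unknown"])

    return CharacteristicsTable(rows=rows, total=total)
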