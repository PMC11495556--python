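"""Time from target-drug therapy start to adverse-event onset.

Onset time is the whole-day difference between the event date and the
earliest therapy start date of the target drug. Cases with a missing or
partial-precision date, or a negative difference, are excluded with a
reason code; same-day onsets (0 days) are kept.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .preprocess import AnalysisCase

__all__ = [
    "DEFAULT_BIN_EDGES",
    "Excluded",
    "OnsetRecord",
    "TTOSummary",
    "bin_label",
    "collect_onsets",
    "compute_tto",
    "summarize_tto",
]

#: Right-closed 30-day-based bin edges: [0-30], (30-60], ..., (180-360], >360.
DEFAULT_BIN_EDGES = (30, 60, 90, 180, 360)


@dataclass(frozen=True, slots=True)
class Excluded:
    """A case excluded from onset analysis, with the reason why."""

    reason: str  # missing_start | missing_event | partial_date | negative


@dataclass(frozen=True, slots=True)
class OnsetRecord:
    primaryid: str
    tto_days: int
    bin: str


def compute_tto(case: AnalysisCase) -> int | Excluded:
    """Days from therapy start to event, or the exclusion reason."""
    if not case.is_target:
        raise ValueError("onset time is only defined for target cases")
    if case.target_start_dt is None:
        return Excluded("missing_start")
    if case.event_dt is None:
        return Excluded("missing_event")
    if case.target_start_dt.precision != "day" or case.event_dt.precision != "day":
        return Excluded("partial_date")
    delta = (case.event_dt.to_date() - case.target_start_dt.to_date()).days
    if delta < 0:
        return Excluded("negative")
    return delta


def bin_label(tto_days: int, edges: Sequence[int] = DEFAULT_BIN_EDGES) -> str:
    lo = 0
    for edge in edges:
        if tto_days <= edge:
            return f"{lo}-{edge}" if lo == 0 else f"{lo + 1}-{edge}"
        lo = edge
    return f">{edges[-1]}"


@dataclass
class TTOSummary:
    n: int
    median: float | None
    bins: list[tuple[str, int, float]]  # (label, count, percent)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.bins, columns=["bin", "count", "percent"])

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.insert(0, "median", self.median)
        df.insert(0, "n", self.n)
        df.to_csv(path, index=False)

    def percent_of(self, label: str) -> float:
        for lab, _, pct in self.bins:
            if lab == label:
                return pct
        raise KeyError(label)


def summarize_tto(
    tto_days: Iterable[int], edges: Sequence[int] = DEFAULT_BIN_EDGES
) -> TTOSummary:
    """Median and 30-day-bin distribution of onset times.

    The median of an even-sized sample is the mean of the two middle
    values; an empty input yields an empty summary, not an error.
    """
    values = sorted(int(v) for v in tto_days)
    if any(v < 0 for v in values):
        raise ValueError("negative onset times must be excluded upstream")
    labels = [bin_label(0 if i == 0 else edges[i - 1] + 1, edges) for i in range(len(edges))]
    labels.append(f">{edges[-1]}")
    if not values:
        return TTOSummary(n=0, median=None, bins=[(lab, 0, 0.0) for lab in labels])
    counts = {lab: 0 for lab in labels}
    for v in values:
        counts[bin_label(v, edges)] += 1
    n = len(values)
    bins = [(lab, counts[lab], round(100.0 * counts[lab] / n, 2)) for lab in labels]
    return TTOSummary(n=n, median=float(statistics.median(values)), bins=bins)


def collect_onsets(
    cases: Sequence[AnalysisCase], edges: Sequence[int] = DEFAULT_BIN_EDGES
) -> tuple[list[OnsetRecord], pd.DataFrame]:
    """Per-case onset records for target cases, plus an audit frame.

    The audit frame has one row per target case with its onset days or the
    exclusion reason, for the per-case onset CSV.
    """
    records: list[OnsetRecord] = []
    audit_rows: list[tuple[str, object, str | None]] = []
    for case in cases:
        if not case.is_target:
            continue
        result = compute_tto(case)
        if isinstance(result, Excluded):
            audit_rows.append((case.primaryid, None, result.reason))
        else:
            records.append(OnsetRecord(case.primaryid, result, bin_label(result, edges)))
            audit_rows.append((case.primaryid, result, None))
    audit = pd.DataFrame(audit_rows, columns=["primaryid", "tto_days", "excluded_reason"])
    return records, audit
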