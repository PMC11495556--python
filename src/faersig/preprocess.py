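"""Case deduplication, target-drug selection, and PT/SOC standardization.

Turns a raw :class:`~faersig.faers_io.CaseRecordBundle` into one
:class:`AnalysisCase` per retained report, with a flow manifest mirroring
the usual spontaneous-report accounting (total reports, after
deduplication, target primary-suspect reports).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .faers_io import (
    CaseRecordBundle,
    DemoRecord,
    DrugRecord,
    ParseLog,
    PartialDate,
    age_to_years,
    norm_text,
)

__all__ = [
    "AnalysisCase",
    "DedupResult",
    "FlowManifest",
    "MeddraMap",
    "assemble_case_table",
    "deduplicate_cases",
    "match_target_drug",
    "standardize_terms",
]


class MeddraMap:
    """PT -> primary SOC lookup (stand-in for a licensed MedDRA table).

    Keys are compared trim/upper-cased; each PT maps to exactly one SOC.
    """

    def __init__(self, entries: Mapping[str, str]):
        self._map: dict[str, str] = {}
        self._display: dict[str, str] = {}
        for pt, soc in entries.items():
            key = norm_text(pt)
            soc = str(soc).strip()
            if not key or not soc:
                raise ValueError("empty PT or SOC in MedDRA map")
            if key in self._map and self._map[key] != soc.upper():
                raise ValueError(f"PT {pt!r} maps to more than one SOC")
            self._map[key] = soc.upper()
            self._display[soc.upper()] = soc
        self.socs = frozenset(self._map.values())

    def __len__(self) -> int:
        return len(self._map)

    def __contains__(self, pt: str) -> bool:
        return norm_text(pt) in self._map

    def soc_of(self, pt: str) -> str | None:
        return self._map.get(norm_text(pt))

    def soc_display(self, soc: str) -> str:
        return self._display.get(norm_text(soc), soc)

    @classmethod
    def from_file(cls, path: str | Path, delimiter: str | None = None) -> "MeddraMap":
        """Load a 2-column (pt, soc) delimited text file with a header."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        if delimiter is None:
            first = text.splitlines()[0] if text else ""
            delimiter = "\t" if "\t" in first else ","
        entries: dict[str, str] = {}
        reader = csv.reader(text.splitlines(), delimiter=delimiter)
        header = next(reader, None)
        if header is None or len(header) < 2:
            raise ValueError(f"{path}: expected a 2-column (pt, soc) header")
        for row in reader:
            if len(row) >= 2 and row[0].strip():
                entries[row[0].strip()] = row[1].strip()
        return cls(entries)


@dataclass(frozen=True, slots=True)
class AnalysisCase:
    """One deduplicated report, ready for screening and descriptives."""

    primaryid: str
    caseid: str
    is_target: bool
    pts: frozenset[str]
    socs: frozenset[str]
    sex: str = "UNK"
    age_years: float | None = None
    country: str | None = None
    occp_cod: str | None = None
    report_year: int | None = None
    outcomes: frozenset[str] = frozenset()
    target_start_dt: PartialDate | None = None
    event_dt: PartialDate | None = None


@dataclass(frozen=True)
class DedupResult:
    retained: frozenset[str]
    removed: int


@dataclass
class FlowManifest:
    """Per-stage record counts of the ingest -> dedup -> filter chain."""

    total_reports: int = 0
    after_dedup: int = 0
    target_ps: int = 0
    dropped_no_pt: int = 0
    unmapped_pts: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "total_reports": self.total_reports,
            "after_dedup": self.after_dedup,
            "target_ps": self.target_ps,
            "dropped_no_pt": self.dropped_no_pt,
            "n_unmapped_pts": len(self.unmapped_pts),
        }


def _dedup_key(rec: DemoRecord) -> tuple[tuple[int, int, int], int | str, str]:
    date_key = rec.fda_dt.sort_key() if rec.fda_dt is not None else (0, 0, 0)
    pid = rec.primaryid
    # numeric primaryids compare numerically; fall back to the string
    num: int | str
    try:
        num = int(pid)
    except ValueError:
        num = pid
    return (date_key, num, pid)


def deduplicate_cases(demo: Sequence[DemoRecord]) -> DedupResult:
    """Keep one report per caseid: latest fda_dt, ties to largest primaryid.

    Missing fda_dt sorts as the earliest possible date so it always loses.
    The rule is deterministic and order-independent.
    """
    if not demo:
        raise ValueError("demo table is empty")
    best: dict[str, DemoRecord] = {}
    for rec in demo:
        cur = best.get(rec.caseid)
        if cur is None or _sortable(_dedup_key(rec)) > _sortable(_dedup_key(cur)):
            best[rec.caseid] = rec
    retained = frozenset(r.primaryid for r in best.values())
    return DedupResult(retained=retained, removed=len(demo) - len(retained))


def _sortable(key: tuple) -> tuple:
    date_key, num, pid = key
    # mixed int/str primaryids: ints rank above any string of same date
    return (date_key, (1, num, "") if isinstance(num, int) else (0, 0, pid))


def match_target_drug(
    drugs: Iterable[DrugRecord],
    names: Sequence[str],
    role: str = "PS",
    substring: bool = False,
) -> set[str]:
    """Return primaryids with a ``role``-coded drug matching any listed name.

    Matching is on drugname or prod_ai after trim/upper-case normalization;
    ``substring=True`` additionally matches names contained in the field.
    """
    norm_names = [norm_text(n) for n in names if norm_text(n)]
    if not norm_names:
        raise ValueError("target name list is empty")
    role = norm_text(role)
    matched: set[str] = set()
    name_set = set(norm_names)
    for drug in drugs:
        if drug.role_cod != role:
            continue
        fields_ = (norm_text(drug.drugname), norm_text(drug.prod_ai))
        if any(f in name_set for f in fields_ if f):
            matched.add(drug.primaryid)
        elif substring and any(n in f for n in norm_names for f in fields_ if f):
            matched.add(drug.primaryid)
    return matched


def standardize_terms(
    pts: Iterable[str], meddra: MeddraMap
) -> tuple[set[str], set[str], list[str]]:
    """Map PTs to SOCs; unmapped PTs are kept at PT level and reported.

    Returns ``(pts_kept, socs, unmapped)``; SOC sets contain only mapped
    terms, so unmapped PTs never invent a SOC assignment.
    """
    if len(meddra) == 0:
        raise ValueError("MedDRA map is empty")
    kept: set[str] = set()
    socs: set[str] = set()
    unmapped: list[str] = []
    for pt in pts:
        key = norm_text(pt)
        if not key:
            continue
        kept.add(key)
        soc = meddra.soc_of(key)
        if soc is None:
            unmapped.append(pt.strip())
        else:
            socs.add(soc)
    return kept, socs, sorted(set(unmapped))


def assemble_case_table(
    bundle: CaseRecordBundle,
    target_names: Sequence[str],
    meddra: MeddraMap,
    role: str = "PS",
    substring: bool = False,
    year_field: str = "fda_dt",
    log: ParseLog | None = None,
) -> tuple[list[AnalysisCase], FlowManifest]:
    """Deduplicate, flag target reports, and standardize terms.

    Produces one :class:`AnalysisCase` per retained report (target and
    non-target alike — non-target reports form the comparator margin of the
    2x2 tables) plus the flow manifest. Reports with no reaction rows are
    dropped with a warning.
    """
    if year_field not in ("fda_dt", "rept_dt"):
        raise ValueError("year_field must be 'fda_dt' or 'rept_dt'")
    log = log if log is not None else ParseLog()
    manifest = FlowManifest(total_reports=len(bundle.demo))

    dedup = deduplicate_cases(bundle.demo)
    manifest.after_dedup = len(dedup.retained)

    matched = match_target_drug(bundle.drugs, target_names, role=role, substring=substring)

    pts_by_id: dict[str, set[str]] = {}
    for reac in bundle.reacs:
        pts_by_id.setdefault(reac.primaryid, set()).add(reac.pt)
    outcs_by_id: dict[str, set[str]] = {}
    for outc in bundle.outcs:
        outcs_by_id.setdefault(outc.primaryid, set()).add(outc.outc_cod)

    # earliest therapy start among the target drug's role-matched rows
    target_seqs: set[tuple[str, int]] = set()
    norm_names = {norm_text(n) for n in target_names}
    for drug in bundle.drugs:
        if drug.role_cod != norm_text(role):
            continue
        if norm_text(drug.drugname) in norm_names or norm_text(drug.prod_ai) in norm_names:
            target_seqs.add((drug.primaryid, drug.drug_seq))
        elif substring:
            fields_ = (norm_text(drug.drugname), norm_text(drug.prod_ai))
            if any(n in f for n in norm_names for f in fields_ if f):
                target_seqs.add((drug.primaryid, drug.drug_seq))
    start_by_id: dict[str, PartialDate] = {}
    for ther in bundle.thers:
        if (ther.primaryid, ther.dsg_drug_seq) in target_seqs and ther.start_dt is not None:
            cur = start_by_id.get(ther.primaryid)
            if cur is None or ther.start_dt.sort_key() < cur.sort_key():
                start_by_id[ther.primaryid] = ther.start_dt

    unmapped_all: set[str] = set()
    cases: list[AnalysisCase] = []
    for rec in bundle.demo:
        if rec.primaryid not in dedup.retained:
            continue
        raw_pts = pts_by_id.get(rec.primaryid)
        if not raw_pts:
            manifest.dropped_no_pt += 1
            log.warn("case_no_pt", f"report {rec.primaryid} has no reactions")
            continue
        pts, socs, unmapped = standardize_terms(raw_pts, meddra)
        unmapped_all.update(unmapped)
        age_years = None
        if rec.age_value is not None:
            age_years = age_to_years(rec.age_value, rec.age_unit, log)
        year_dt = rec.fda_dt if year_field == "fda_dt" else rec.rept_dt
        is_target = rec.primaryid in matched
        cases.append(AnalysisCase(
            primaryid=rec.primaryid,
            caseid=rec.caseid,
            is_target=is_target,
            pts=frozenset(pts),
            socs=frozenset(socs),
            sex=rec.sex,
            age_years=age_years,
            country=rec.reporter_country,
            occp_cod=rec.occp_cod,
            report_year=year_dt.year if year_dt is not None else None,
            outcomes=frozenset(outcs_by_id.get(rec.primaryid, set())),
            target_start_dt=start_by_id.get(rec.primaryid) if is_target else None,
            event_dt=rec.event_dt,
        ))
        if is_target:
            manifest.target_ps += 1
    manifest.unmapped_pts = sorted(unmapped_all)
    return cases, manifest
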