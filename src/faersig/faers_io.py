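"""Reading and writing the FAERS quarterly ASCII ("$"-delimited) dialect.

The five per-quarter tables (DEMO, DRUG, REAC, THER, OUTC) are parsed into
typed records.  Field normalization happens here: dates become
:class:`PartialDate` values carrying their precision, ages keep their raw
value/unit pair (see :func:`age_to_years`), and code fields are validated
against the FAERS enumerations.  Malformed rows are never silently dropped:
every rejection and soft repair is counted in a :class:`ParseLog`.
"""

from __future__ import annotations

import csv
import datetime
from collections import Counter
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "AGE_UNIT_FACTORS",
    "OCCP_CODES",
    "OUTCOME_CODES",
    "ROLE_CODES",
    "SEX_CODES",
    "CaseRecordBundle",
    "DemoRecord",
    "DrugRecord",
    "OutcRecord",
    "ParseLog",
    "PartialDate",
    "ReacRecord",
    "TherRecord",
    "age_to_years",
    "norm_text",
    "parse_faers_date",
    "read_quarter_tables",
    "write_quarter_tables",
]

ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})
SEX_CODES = frozenset({"M", "F", "UNK"})
OCCP_CODES = frozenset({"MD", "PH", "OT", "CN", "HP"})

#: Conversion factors from FAERS age units to years.
AGE_UNIT_FACTORS: Mapping[str, float] = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}


def norm_text(value: str | None) -> str:
    """Normalize a key for comparison: trim and upper-case."""
    return (value or "").strip().upper()


@dataclass(frozen=True, slots=True, order=False)
class PartialDate:
    """A calendar date at year, month, or day precision."""

    year: int
    month: int | None = None
    day: int | None = None

    @property
    def precision(self) -> str:
        if self.day is not None:
            return "day"
        if self.month is not None:
            return "month"
        return "year"

    def sort_key(self) -> tuple[int, int, int]:
        return (self.year, self.month or 0, self.day or 0)

    def to_date(self) -> datetime.date:
        if self.precision != "day":
            raise ValueError(f"date {self} has {self.precision} precision, not day")
        return datetime.date(self.year, self.month, self.day)  # type: ignore[arg-type]

    def serialize(self) -> str:
        if self.day is not None:
            return f"{self.year:04d}{self.month:02d}{self.day:02d}"
        if self.month is not None:
            return f"{self.year:04d}{self.month:02d}"
        return f"{self.year:04d}"


@dataclass
class ParseLog:
    """Counters for rejected rows and soft-repair warnings."""

    rejected: Counter = field(default_factory=Counter)
    warnings: Counter = field(default_factory=Counter)
    messages: list[str] = field(default_factory=list)
    _max_messages: int = 200

    def warn(self, category: str, message: str = "") -> None:
        self.warnings[category] += 1
        if message and len(self.messages) < self._max_messages:
            self.messages.append(f"[warn:{category}] {message}")

    def reject(self, table: str, message: str = "") -> None:
        self.rejected[table] += 1
        if message and len(self.messages) < self._max_messages:
            self.messages.append(f"[reject:{table}] {message}")

    @property
    def n_rejected(self) -> int:
        return sum(self.rejected.values())

    @property
    def n_warnings(self) -> int:
        return sum(self.warnings.values())


def parse_faers_date(raw: str | None, log: ParseLog | None = None) -> PartialDate | None:
    """Parse a FAERS date string (YYYYMMDD / YYYYMM / YYYY / empty).

    Invalid calendar values (month 13, day 32) and non-digit input yield
    ``None`` with a warning — never a fatal error.
    """
    raw = (raw or "").strip()
    if not raw:
        return None
    if not raw.isdigit() or len(raw) not in (4, 6, 8):
        if log is not None:
            log.warn("bad_date", f"unparseable date {raw!r}")
        return None
    year = int(raw[:4])
    if len(raw) == 4:
        return PartialDate(year)
    month = int(raw[4:6])
    if not 1 <= month <= 12:
        if log is not None:
            log.warn("bad_date", f"invalid month in {raw!r}")
        return None
    if len(raw) == 6:
        return PartialDate(year, month)
    day = int(raw[6:8])
    try:
        datetime.date(year, month, day)
    except ValueError:
        if log is not None:
            log.warn("bad_date", f"invalid day in {raw!r}")
        return None
    return PartialDate(year, month, day)


def age_to_years(value: float, unit: str | None, log: ParseLog | None = None) -> float:
    """Convert a FAERS (age, unit) pair to years.

    A missing unit is treated as years, with a warning: the value alone is
    almost always a year count in practice and discarding it loses data.
    """
    if value < 0:
        raise ValueError("age value must be >= 0")
    unit = norm_text(unit) or None
    if unit is None:
        if log is not None:
            log.warn("missing_age_unit", "age unit missing, assuming years")
        return float(value)
    if unit not in AGE_UNIT_FACTORS:
        raise ValueError(f"unknown age unit {unit!r}")
    return float(value) * AGE_UNIT_FACTORS[unit]


@dataclass(frozen=True, slots=True)
class DemoRecord:
    primaryid: str
    caseid: str
    caseversion: int = 1
    fda_dt: PartialDate | None = None
    event_dt: PartialDate | None = None
    rept_dt: PartialDate | None = None
    age_value: float | None = None
    age_unit: str | None = None
    sex: str = "UNK"
    reporter_country: str | None = None
    occp_cod: str | None = None


@dataclass(frozen=True, slots=True)
class DrugRecord:
    primaryid: str
    drug_seq: int
    role_cod: str
    drugname: str
    prod_ai: str | None = None


@dataclass(frozen=True, slots=True)
class ReacRecord:
    primaryid: str
    pt: str


@dataclass(frozen=True, slots=True)
class TherRecord:
    primaryid: str
    dsg_drug_seq: int
    start_dt: PartialDate | None = None
    end_dt: PartialDate | None = None


@dataclass(frozen=True, slots=True)
class OutcRecord:
    primaryid: str
    outc_cod: str


@dataclass
class CaseRecordBundle:
    """The five linked per-quarter report tables keyed by primaryid."""

    demo: list[DemoRecord] = field(default_factory=list)
    drugs: list[DrugRecord] = field(default_factory=list)
    reacs: list[ReacRecord] = field(default_factory=list)
    thers: list[TherRecord] = field(default_factory=list)
    outcs: list[OutcRecord] = field(default_factory=list)
    quarter_label: str = ""

    def validate(self) -> None:
        """Raise ValueError on any violated bundle invariant."""
        ids = [r.primaryid for r in self.demo]
        known = set(ids)
        if len(ids) != len(known):
            raise ValueError("duplicate primaryid in demo table")
        for name in ("drugs", "reacs", "thers", "outcs"):
            for rec in getattr(self, name):
                if rec.primaryid not in known:
                    raise ValueError(f"{name} row {rec.primaryid!r} missing from demo")
        seen_seq: set[tuple[str, int]] = set()
        for drug in self.drugs:
            key = (drug.primaryid, drug.drug_seq)
            if key in seen_seq:
                raise ValueError(f"duplicate (primaryid, drug_seq) {key}")
            seen_seq.add(key)

    def __len__(self) -> int:
        return len(self.demo)


# column layout of each table in the supported dialect
_DEMO_COLS = ("primaryid", "caseid", "caseversion", "fda_dt", "event_dt",
              "rept_dt", "age", "age_cod", "sex", "reporter_country", "occp_cod")
_DRUG_COLS = ("primaryid", "drug_seq", "role_cod", "drugname", "prod_ai")
_REAC_COLS = ("primaryid", "pt")
_THER_COLS = ("primaryid", "dsg_drug_seq", "start_dt", "end_dt")
_OUTC_COLS = ("primaryid", "outc_cod")

TABLE_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "demo": _DEMO_COLS,
    "drug": _DRUG_COLS,
    "reac": _REAC_COLS,
    "ther": _THER_COLS,
    "outc": _OUTC_COLS,
}

DELIMITER = "$"


def _read_rows(path: Path, table: str, log: ParseLog) -> Iterable[dict[str, str]]:
    required = TABLE_COLUMNS[table]
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=DELIMITER)
        try:
            header = [h.strip().lower() for h in next(reader)]
        except StopIteration:
            raise ValueError(f"{path}: empty file, header expected") from None
        index = {name: header.index(name) for name in header}
        for col in required:
            if col not in index:
                raise ValueError(f"{path}: required column {col!r} missing")
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < len(header):
                log.reject(table, f"{path.name}:{lineno} short row")
                continue
            yield {col: row[index[col]].strip() for col in required}


def _opt(value: str) -> str | None:
    return value if value else None


def read_quarter_tables(
    paths: Mapping[str, str | Path],
    quarter_label: str = "",
    log: ParseLog | None = None,
) -> tuple[CaseRecordBundle, ParseLog]:
    """Read the five quarterly tables into a validated bundle.

    ``paths`` maps the table keys ``demo/drug/reac/ther/outc`` to files.
    A missing required column is fatal; a malformed field inside a row is
    either repaired to missing (dates, ages) or rejects the row (bad enum
    codes, empty keys), always counted in the returned :class:`ParseLog`.
    Rows in the satellite tables whose primaryid has no DEMO row are
    rejected so the bundle invariants hold by construction.
    """
    log = log if log is not None else ParseLog()
    for key in TABLE_COLUMNS:
        if key not in paths:
            raise ValueError(f"no path given for table {key!r}")
        if not Path(paths[key]).exists():
            raise FileNotFoundError(f"{key} table not found: {paths[key]}")

    bundle = CaseRecordBundle(quarter_label=quarter_label)
    known: set[str] = set()

    for row in _read_rows(Path(paths["demo"]), "demo", log):
        pid, caseid = row["primaryid"], row["caseid"]
        if not pid or not caseid:
            log.reject("demo", "empty primaryid/caseid")
            continue
        if pid in known:
            log.reject("demo", f"duplicate primaryid {pid}")
            continue
        try:
            caseversion = int(row["caseversion"]) if row["caseversion"] else 1
        except ValueError:
            caseversion = 1
            log.warn("bad_caseversion", row["caseversion"])
        age_value: float | None = None
        if row["age"]:
            try:
                age_value = float(row["age"])
                if age_value < 0:
                    raise ValueError
            except ValueError:
                age_value = None
                log.warn("bad_age", row["age"])
        age_unit = norm_text(row["age_cod"]) or None
        if age_unit is not None and age_unit not in AGE_UNIT_FACTORS:
            log.warn("bad_age_unit", age_unit)
            age_unit = None
        sex = norm_text(row["sex"])
        if sex not in SEX_CODES:
            if sex:
                log.warn("bad_sex", sex)
            sex = "UNK"
        occp = norm_text(row["occp_cod"]) or None
        if occp is not None and occp not in OCCP_CODES:
            log.warn("bad_occp", occp)
            occp = None
        bundle.demo.append(DemoRecord(
            primaryid=pid,
            caseid=caseid,
            caseversion=caseversion,
            fda_dt=parse_faers_date(row["fda_dt"], log),
            event_dt=parse_faers_date(row["event_dt"], log),
            rept_dt=parse_faers_date(row["rept_dt"], log),
            age_value=age_value,
            age_unit=age_unit,
            sex=sex,
            reporter_country=_opt(row["reporter_country"]),
            occp_cod=occp,
        ))
        known.add(pid)

    for row in _read_rows(Path(paths["drug"]), "drug", log):
        pid = row["primaryid"]
        role = norm_text(row["role_cod"])
        if pid not in known:
            log.reject("drug", f"orphan primaryid {pid}")
            continue
        if role not in ROLE_CODES:
            log.reject("drug", f"bad role_cod {role!r}")
            continue
        try:
            seq = int(row["drug_seq"])
        except ValueError:
            log.reject("drug", f"bad drug_seq {row['drug_seq']!r}")
            continue
        bundle.drugs.append(DrugRecord(
            primaryid=pid, drug_seq=seq, role_cod=role,
            drugname=row["drugname"], prod_ai=_opt(row["prod_ai"]),
        ))

    for row in _read_rows(Path(paths["reac"]), "reac", log):
        pid, pt = row["primaryid"], row["pt"].strip()
        if pid not in known:
            log.reject("reac", f"orphan primaryid {pid}")
            continue
        if not pt:
            log.reject("reac", "empty pt")
            continue
        bundle.reacs.append(ReacRecord(primaryid=pid, pt=pt))

    for row in _read_rows(Path(paths["ther"]), "ther", log):
        pid = row["primaryid"]
        if pid not in known:
            log.reject("ther", f"orphan primaryid {pid}")
            continue
        try:
            seq = int(row["dsg_drug_seq"])
        except ValueError:
            log.reject("ther", f"bad dsg_drug_seq {row['dsg_drug_seq']!r}")
            continue
        bundle.thers.append(TherRecord(
            primaryid=pid, dsg_drug_seq=seq,
            start_dt=parse_faers_date(row["start_dt"], log),
            end_dt=parse_faers_date(row["end_dt"], log),
        ))

    for row in _read_rows(Path(paths["outc"]), "outc", log):
        pid = row["primaryid"]
        code = norm_text(row["outc_cod"])
        if pid not in known:
            log.reject("outc", f"orphan primaryid {pid}")
            continue
        if code not in OUTCOME_CODES:
            log.reject("outc", f"bad outc_cod {code!r}")
            continue
        bundle.outcs.append(OutcRecord(primaryid=pid, outc_cod=code))

    return bundle, log


def _ser_date(dt: PartialDate | None) -> str:
    return dt.serialize() if dt is not None else ""


def _ser(value: object) -> str:
    if value is None:
        return ""
    if isinstance(value, PartialDate):
        return value.serialize()
    if isinstance(value, float):
        return format(value, "g")
    return str(value)


def write_quarter_tables(bundle: CaseRecordBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle back to the five "$"-delimited files.

    Dates are serialized at their stored precision; the output re-reads to
    an identical bundle (round-trip identity).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = {"demo": bundle.demo, "drug": bundle.drugs, "reac": bundle.reacs,
              "ther": bundle.thers, "outc": bundle.outcs}
    # DEMO field names differ from the column header (age/age_cod)
    attr_map = {
        "demo": ("primaryid", "caseid", "caseversion", "fda_dt", "event_dt",
                 "rept_dt", "age_value", "age_unit", "sex", "reporter_country",
                 "occp_cod"),
        "drug": _DRUG_COLS,
        "reac": _REAC_COLS,
        "ther": _THER_COLS,
        "outc": _OUTC_COLS,
    }
    paths: dict[str, Path] = {}
    for table, records in tables.items():
        path = out_dir / f"{table}.txt"
        cols = TABLE_COLUMNS[table]
        attrs = attr_map[table]
        with open(path, "w", newline="", encoding="utf-8") as fh:
            fh.write(DELIMITER.join(cols) + "\n")
            for rec in records:
                fh.write(DELIMITER.join(_ser(getattr(rec, at)) for at in attrs) + "\n")
        paths[table] = path
    return paths
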