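"""Synthetic spontaneous-report generator with known ground truth.

Emits FAERS-like bundles whose drug-event reporting-rate ratios, duplicate
linkage, onset-time distribution and demographics are all planted by
configuration, so every pipeline stage can be exercised and checked
against the truth without any external download.

Event sampling: a report exposed to the target drug draws its events
without replacement with weights ``baseline[j] * lambda[j]`` (renormalized);
other reports use the baseline weights. The planted ratio therefore maps to
an expected observed/expected ratio of ``lambda / Z`` with
``Z = sum(baseline * lambda)``, diluted by the target share of the database
(see :meth:`GroundTruth.expected_ebgm`).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .faers_io import (
    CaseRecordBundle,
    DemoRecord,
    DrugRecord,
    OutcRecord,
    PartialDate,
    ReacRecord,
    TherRecord,
    write_quarter_tables,
)
from .preprocess import MeddraMap

__all__ = [
    "GroundTruth",
    "RecoveryReport",
    "SyntheticConfig",
    "generate_dataset",
    "planted_truth_check",
]

_EVENTS_CAP = 8  # hard cap on events per report


def _zipf_probs(n_pts: int, s: float) -> np.ndarray:
    ranks = np.arange(1, n_pts + 1, dtype=float)
    w = ranks ** (-s)
    return w / w.sum()


@dataclass
class SyntheticConfig:
    """Generative-model parameters; every distribution is configurable."""

    n_reports: int = 10_000
    p_target: float = 0.02
    n_pts: int = 200
    n_socs: int = 15
    zipf_s: float = 1.0
    baseline_probs: Sequence[float] | None = None
    planted: Mapping[str, float] = field(default_factory=dict)  # PT name -> rate ratio
    events_mean: float = 3.0
    dup_fraction: float = 0.05
    missing_rates: Mapping[str, float] = field(default_factory=lambda: {
        "event_dt": 0.30,
        "start_dt": 0.15,
        "start_dt_month": 0.10,  # degrade start date to month precision
        "age": 0.25,
        "occp": 0.05,
        "country": 0.01,
        "rept_dt": 0.10,
    })
    tto_median_days: float = 60.0
    tto_sigma: float = 1.0
    sex_probs: Mapping[str, float] = field(default_factory=lambda: {
        "M": 0.92, "F": 0.05, "UNK": 0.03})
    age_mean: float = 72.0
    age_sd: float = 12.0
    country_probs: Mapping[str, float] = field(default_factory=lambda: {
        "US": 0.90, "JP": 0.04, "DE": 0.02, "GB": 0.02, "SE": 0.01, "PT": 0.01})
    occp_probs: Mapping[str, float] = field(default_factory=lambda: {
        "CN": 0.75, "HP": 0.10, "MD": 0.08, "PH": 0.03, "OT": 0.04})
    outcome_rate: float = 0.25
    outcome_probs: Mapping[str, float] = field(default_factory=lambda: {
        "OT": 0.40, "HO": 0.30, "DE": 0.20, "LT": 0.04, "DS": 0.04, "RI": 0.02})
    target_names: Sequence[str] = ("RELUGOLIX", "ORGOVYX")
    n_decoy_drugs: int = 50
    concomitant_rate: float = 0.30
    start_window: tuple[str, str] = ("2020-10-01", "2023-06-30")
    quarter_label: str = "2023Q3"
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports <= 0:
            raise ValueError("n_reports must be positive")
        if not 0.0 <= self.p_target <= 1.0 or not 0.0 <= self.dup_fraction <= 1.0:
            raise ValueError("probabilities must be in [0, 1]")
        if min(_EVENTS_CAP, math.ceil(self.events_mean)) > self.n_pts:
            raise ValueError("events per report can exceed the PT vocabulary")
        if len(self.planted) > self.n_pts:
            raise ValueError("more planted PTs than the vocabulary size")
        probs = self.baseline()
        if len(probs) != self.n_pts:
            raise ValueError("baseline_probs length must equal n_pts")
        if abs(probs.sum() - 1.0) > 1e-9 or (probs < 0).any():
            raise ValueError("baseline_probs must be a probability vector")
        for name in self.planted:
            if self.planted[name] < 0:
                raise ValueError("planted rate ratios must be >= 0")
            if self.pt_index(name) is None:
                raise ValueError(f"planted PT {name!r} not in vocabulary")

    def baseline(self) -> np.ndarray:
        if self.baseline_probs is not None:
            arr = np.asarray(self.baseline_probs, dtype=float)
            return arr / arr.sum()
        return _zipf_probs(self.n_pts, self.zipf_s)

    def pt_names(self) -> list[str]:
        return [f"PT{j + 1:04d}" for j in range(self.n_pts)]

    def pt_index(self, name: str) -> int | None:
        name = name.strip().upper()
        names = self.pt_names()
        try:
            return names.index(name)
        except ValueError:
            return None

    def pt_soc_map(self) -> dict[str, str]:
        return {f"PT{j + 1:04d}": f"SOC{(j % self.n_socs) + 1:02d}"
                for j in range(self.n_pts)}

    def lambda_vec(self) -> np.ndarray:
        lam = np.ones(self.n_pts)
        for name, value in self.planted.items():
            lam[self.pt_index(name)] = value  # validated upstream
        return lam

    @classmethod
    def from_dict(cls, data: Mapping) -> "SyntheticConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown synthetic config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    config: SyntheticConfig
    lambda_vec: np.ndarray
    baseline: np.ndarray
    pt_soc: dict[str, str]
    duplicate_pairs: list[tuple[str, str]]  # (original, duplicate) primaryids
    true_tto: dict[str, int]  # target primaryid -> onset days before noising

    @property
    def renorm(self) -> float:
        """Z = sum(baseline * lambda): the weight renormalization factor."""
        return float(np.dot(self.baseline, self.lambda_vec))

    def expected_ebgm(self, pt: str) -> float:
        """Expected observed/expected ratio for a planted PT.

        lambda/Z among target reports, diluted because target reports also
        contribute to the overall margin.
        """
        j = self.config.pt_index(pt)
        if j is None:
            raise KeyError(pt)
        lam_z = self.lambda_vec[j] / self.renorm
        p = self.config.p_target
        return lam_z / (p * lam_z + (1.0 - p))

    def expected_a(self, pt: str) -> float:
        """Approximate expected target case count for a PT."""
        j = self.config.pt_index(pt)
        if j is None:
            raise KeyError(pt)
        p_draw = self.baseline[j] * self.lambda_vec[j] / self.renorm
        p_case = 1.0 - (1.0 - p_draw) ** self.config.events_mean
        return self.config.n_reports * self.config.p_target * p_case

    def meddra_map(self) -> MeddraMap:
        return MeddraMap(self.pt_soc)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.config.seed,
            "n_reports": self.config.n_reports,
            "p_target": self.config.p_target,
            "planted": dict(self.config.planted),
            "renorm": self.renorm,
            "duplicate_pairs": self.duplicate_pairs,
            "true_tto": self.true_tto,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def _sample_events(
    rng: np.random.Generator,
    is_target: np.ndarray,
    k: np.ndarray,
    baseline: np.ndarray,
    lam: np.ndarray,
    chunk: int = 50_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted sampling without replacement per report (exponential-race).

    Drawing the k smallest of Exp(1)/w_j keys is equivalent to successive
    weighted draws without replacement. Returns (report_idx, pt_idx) pairs.
    """
    n, n_pts = len(k), len(baseline)
    w_target = baseline * lam
    rows_out: list[np.ndarray] = []
    cols_out: list[np.ndarray] = []
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        m = hi - lo
        weights = np.where(is_target[lo:hi, None], w_target[None, :], baseline[None, :])
        with np.errstate(divide="ignore"):
            keys = rng.exponential(size=(m, n_pts)) / weights  # zero weight -> inf key
        kmax = int(k[lo:hi].max())
        part = np.argpartition(keys, kmax - 1, axis=1)[:, :kmax] if kmax < n_pts \
            else np.argsort(keys, axis=1)[:, :kmax]
        vals = np.take_along_axis(keys, part, axis=1)
        order = np.argsort(vals, axis=1)
        cols_sorted = np.take_along_axis(part, order, axis=1)
        mask = np.arange(kmax)[None, :] < k[lo:hi, None]
        rows = np.repeat(np.arange(lo, hi), kmax).reshape(m, kmax)
        rows_out.append(rows[mask])
        cols_out.append(cols_sorted[mask])
    return np.concatenate(rows_out), np.concatenate(cols_out)


def _categorical(rng: np.random.Generator, probs: Mapping[str, float], n: int) -> np.ndarray:
    keys = list(probs)
    p = np.array([probs[key] for key in keys], dtype=float)
    return np.array(keys, dtype=object)[rng.choice(len(keys), size=n, p=p / p.sum())]


def _split_dates(days: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    idx = pd.DatetimeIndex(days.astype("datetime64[ns]"))
    return idx.year.to_numpy(), idx.month.to_numpy(), idx.day.to_numpy()


def generate_dataset(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> tuple[CaseRecordBundle, GroundTruth]:
    """Generate a FAERS-like bundle plus its ground truth.

    Fully reproducible from ``config.seed``; with ``out_dir`` given, the
    five "$"-delimited tables, the PT->SOC map and a ground-truth sidecar
    are also written to disk.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    baseline = config.baseline()
    lam = config.lambda_vec()
    pt_names = np.array(config.pt_names(), dtype=object)

    is_target = rng.random(n) < config.p_target
    k = np.clip(rng.poisson(config.events_mean, n), 1, min(_EVENTS_CAP, config.n_pts))
    ev_rows, ev_cols = _sample_events(rng, is_target, k, baseline, lam)

    # dates: therapy start uniform in the window, event = start + onset
    w0 = np.datetime64(config.start_window[0], "D")
    w1 = np.datetime64(config.start_window[1], "D")
    window = int((w1 - w0) / np.timedelta64(1, "D")) + 1
    start = w0 + rng.integers(0, window, n).astype("timedelta64[D]")
    tto = np.rint(rng.lognormal(math.log(config.tto_median_days), config.tto_sigma, n)).astype(int)
    event = start + tto.astype("timedelta64[D]")
    fda = event + rng.integers(7, 61, n).astype("timedelta64[D]")
    rept = fda + rng.integers(0, 15, n).astype("timedelta64[D]")

    sex = _categorical(rng, config.sex_probs, n)
    age_years = np.clip(np.rint(rng.normal(config.age_mean, config.age_sd, n)), 18, 100)
    age_unit = _categorical(rng, {"YR": 0.90, "DEC": 0.05, "MON": 0.05}, n)
    country = _categorical(rng, config.country_probs, n)
    occp = _categorical(rng, config.occp_probs, n)
    has_outc = rng.random(n) < config.outcome_rate
    outc = _categorical(rng, config.outcome_probs, n)

    mr = config.missing_rates
    miss_event = rng.random(n) < mr.get("event_dt", 0.0)
    miss_start = rng.random(n) < mr.get("start_dt", 0.0)
    month_start = rng.random(n) < mr.get("start_dt_month", 0.0)
    miss_age = rng.random(n) < mr.get("age", 0.0)
    miss_occp = rng.random(n) < mr.get("occp", 0.0)
    miss_country = rng.random(n) < mr.get("country", 0.0)
    miss_rept = rng.random(n) < mr.get("rept_dt", 0.0)

    target_choice = rng.integers(0, len(config.target_names), n)
    decoy = rng.integers(1, config.n_decoy_drugs + 1, n)
    has_conc = rng.random(n) < config.concomitant_rate
    conc_decoy = rng.integers(1, config.n_decoy_drugs + 1, n)

    sy, sm, sd = _split_dates(start)
    ey, em, ed = _split_dates(event)
    fy, fm, fd = _split_dates(fda)
    ry, rm, rd = _split_dates(rept)

    primaryids = [str(100_000_000 + i) for i in range(n)]
    caseids = [str(70_000_000 + i) for i in range(n)]

    bundle = CaseRecordBundle(quarter_label=config.quarter_label)
    true_tto: dict[str, int] = {}
    target_name_list = [str(t).upper() for t in config.target_names]

    for i in range(n):
        pid = primaryids[i]
        unit = str(age_unit[i])
        if unit == "YR":
            age_val = float(age_years[i])
        elif unit == "DEC":
            age_val = round(age_years[i] / 10.0, 1)
        else:  # MON
            age_val = float(age_years[i] * 12)
        bundle.demo.append(DemoRecord(
            primaryid=pid,
            caseid=caseids[i],
            caseversion=1,
            fda_dt=PartialDate(int(fy[i]), int(fm[i]), int(fd[i])),
            event_dt=None if miss_event[i] else PartialDate(int(ey[i]), int(em[i]), int(ed[i])),
            rept_dt=None if miss_rept[i] else PartialDate(int(ry[i]), int(rm[i]), int(rd[i])),
            age_value=None if miss_age[i] else age_val,
            age_unit=None if miss_age[i] else unit,
            sex=str(sex[i]),
            reporter_country=None if miss_country[i] else str(country[i]),
            occp_cod=None if miss_occp[i] else str(occp[i]),
        ))
        if is_target[i]:
            name = target_name_list[target_choice[i]]
            bundle.drugs.append(DrugRecord(pid, 1, "PS", name, target_name_list[0]))
            true_tto[pid] = int(tto[i])
        else:
            name = f"DECOY{decoy[i]:03d}"
            bundle.drugs.append(DrugRecord(pid, 1, "PS", name, name))
        if has_conc[i]:
            cname = f"DECOY{conc_decoy[i]:03d}"
            bundle.drugs.append(DrugRecord(pid, 2, "C", cname, cname))
        if not miss_start[i]:
            start_dt = PartialDate(int(sy[i]), int(sm[i])) if month_start[i] \
                else PartialDate(int(sy[i]), int(sm[i]), int(sd[i]))
            bundle.thers.append(TherRecord(pid, 1, start_dt=start_dt))
        if has_outc[i]:
            bundle.outcs.append(OutcRecord(pid, str(outc[i])))

    for row, col in zip(ev_rows, ev_cols):
        bundle.reacs.append(ReacRecord(primaryids[row], str(pt_names[col])))

    # duplicates: re-emit selected cases with a new, larger primaryid,
    # incremented caseversion and fda_dt + 30 days
    n_dup = int(round(config.dup_fraction * n))
    duplicate_pairs: list[tuple[str, str]] = []
    if n_dup:
        dup_idx = np.sort(rng.choice(n, size=n_dup, replace=False))
        by_id_drugs: dict[str, list[DrugRecord]] = {}
        for rec in bundle.drugs:
            by_id_drugs.setdefault(rec.primaryid, []).append(rec)
        by_id_reacs: dict[str, list[ReacRecord]] = {}
        for rec in bundle.reacs:
            by_id_reacs.setdefault(rec.primaryid, []).append(rec)
        by_id_thers: dict[str, list[TherRecord]] = {}
        for rec in bundle.thers:
            by_id_thers.setdefault(rec.primaryid, []).append(rec)
        by_id_outcs: dict[str, list[OutcRecord]] = {}
        for rec in bundle.outcs:
            by_id_outcs.setdefault(rec.primaryid, []).append(rec)
        dfy, dfm, dfd = _split_dates(fda[dup_idx] + np.timedelta64(30, "D"))
        for pos, i in enumerate(dup_idx):
            old = primaryids[i]
            new = str(500_000_000 + int(i))
            demo = bundle.demo[i]
            bundle.demo.append(dataclasses.replace(
                demo, primaryid=new, caseversion=demo.caseversion + 1,
                fda_dt=PartialDate(int(dfy[pos]), int(dfm[pos]), int(dfd[pos])),
            ))
            for rec in by_id_drugs.get(old, []):
                bundle.drugs.append(dataclasses.replace(rec, primaryid=new))
            for rec in by_id_reacs.get(old, []):
                bundle.reacs.append(dataclasses.replace(rec, primaryid=new))
            for rec in by_id_thers.get(old, []):
                bundle.thers.append(dataclasses.replace(rec, primaryid=new))
            for rec in by_id_outcs.get(old, []):
                bundle.outcs.append(dataclasses.replace(rec, primaryid=new))
            duplicate_pairs.append((old, new))
            if old in true_tto:
                true_tto[new] = true_tto[old]

    truth = GroundTruth(
        config=config,
        lambda_vec=lam,
        baseline=baseline,
        pt_soc=config.pt_soc_map(),
        duplicate_pairs=duplicate_pairs,
        true_tto=true_tto,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_quarter_tables(bundle, out_dir)
        with open(out_dir / "meddra_map.csv", "w", encoding="utf-8") as fh:
            fh.write("pt,soc\n")
            for pt, soc in truth.pt_soc.items():
                fh.write(f"{pt},{soc}\n")
        truth.to_json(out_dir / "ground_truth.json")

    return bundle, truth


@dataclass
class RecoveryReport:
    planted: list[dict]
    null_fp_rate: float
    n_null: int
    ok: bool

    def as_dict(self) -> dict:
        return {"planted": self.planted, "null_fp_rate": self.null_fp_rate,
                "n_null": self.n_null, "ok": self.ok}


def planted_truth_check(
    signals: pd.DataFrame,
    truth: GroundTruth,
    tolerance: float = 0.30,
    fp_budget: float = 0.02,
    min_lambda: float = 5.0,
    min_expected_a: float = 50.0,
) -> RecoveryReport:
    """Compare a PT-level screen against the planted ground truth.

    Planted PTs with a strong, well-powered signal (lambda >= ``min_lambda``
    and expected case count >= ``min_expected_a``) must recover an EBGM
    within ``tolerance`` (relative) of the renormalization-adjusted planted
    ratio; null PTs must be flagged significant at a rate <= ``fp_budget``.
    """
    by_term = {str(t).upper(): row for t, row in zip(signals["term"], signals.to_dict("records"))}
    planted_rows: list[dict] = []
    ok = True
    checked_names = set()
    for pt, lam in truth.config.planted.items():
        name = pt.strip().upper()
        checked_names.add(name)
        expected_a = truth.expected_a(name)
        if lam < min_lambda or expected_a < min_expected_a:
            continue
        expected = truth.expected_ebgm(name)
        row = by_term.get(name)
        observed = float(row["ebgm"]) if row is not None else float("nan")
        within = bool(row is not None and abs(observed - expected) <= tolerance * expected)
        ok &= within
        planted_rows.append({
            "pt": name, "lambda": lam, "expected_ebgm": expected,
            "observed_ebgm": observed, "expected_a": expected_a,
            "observed_a": int(row["a"]) if row is not None else 0,
            "significant": bool(row["significant"]) if row is not None else False,
            "within_tolerance": within,
        })
    null_terms = [t for t in by_term if t not in checked_names]
    n_sig = sum(bool(by_term[t]["significant"]) for t in null_terms)
    fp_rate = n_sig / len(null_terms) if null_terms else 0.0
    ok &= fp_rate <= fp_budget
    return RecoveryReport(planted=planted_rows, null_fp_rate=fp_rate,
                          n_null=len(null_terms), ok=ok)
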