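"""Disproportionality screening: 2x2 tables and the four classic algorithms.

For one (drug, event) pair with contingency cells

    a  = reports with target drug AND the event
    b  = reports with target drug, other events
    c  = other drugs with the event
    d  = other drugs, other events        (N = a+b+c+d)

the four statistics and their screening criteria are

    ROR   = ad/(bc),     95% CI = exp(ln ROR +- 1.96*sqrt(1/a+1/b+1/c+1/d))
                         signal if CI lower bound > 1 and a >= 3
    PRR   = a(c+d)/(c(a+b)), with Pearson chi2;  signal if PRR >= 2,
                         chi2 >= 4 and a >= 3
    IC    = log2(aN/((a+b)(a+c)))  (simplified information component);
                         IC025 = IC - 2*sqrt(V) with V from the Bate et al.
                         (1998) moment approximation; signal if IC025 > 0
    EBGM  = aN/((a+b)(a+c))  (simplified observed/expected ratio, no
                         shrinkage), log-normal CI like the ROR;
                         signal if EBGM05 > 2

IC == log2(EBGM) by construction: both are the same observed-to-expected
ratio on different scales.

Scalar functions operate on one :class:`ContingencyTable`;
:func:`screen_signals` is the vectorized screen over every observed term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .faers_io import norm_text
from .preprocess import AnalysisCase, MeddraMap

__all__ = [
    "DEFAULT_EXCLUDED_SOCS",
    "ContingencyTable",
    "Level",
    "SignalDecision",
    "SignalStats",
    "Unit",
    "ZeroCellPolicy",
    "build_contingency",
    "compute_all",
    "compute_bcpnn",
    "compute_ebgm",
    "compute_prr_chi2",
    "compute_ror",
    "evaluate_criteria",
    "flag_unexpected",
    "ic_from_ebgm",
    "reconstruct_cells",
    "ror_from_ci",
    "screen_signals",
]

_Z = 1.96
_LN2 = math.log(2.0)

#: SOC groups conventionally excluded as unrelated to drug treatment
#: (product/quality issues, injuries and procedural complications,
#: surgical and medical procedures).
DEFAULT_EXCLUDED_SOCS = (
    "Product issues",
    "Injury, poisoning and procedural complications",
    "Surgical and medical procedures",
)


class Unit(str, Enum):
    REPORT = "report"
    PAIR = "drug_event_pair"


class Level(str, Enum):
    PT = "PT"
    SOC = "SOC"


@dataclass(frozen=True, slots=True)
class ContingencyTable:
    a: int
    b: int
    c: int
    d: int
    unit: Unit = Unit.PAIR
    level: Level = Level.PT
    term: str = ""

    def __post_init__(self) -> None:
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0:
                raise ValueError("contingency cells must be >= 0")
        if self.n == 0:
            raise ValueError("empty contingency table (N == 0)")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True, slots=True)
class ZeroCellPolicy:
    """How to treat tables with a zero in b, c, or d.

    ``undefined`` flags the row as not computable (it then fails every
    criterion); ``haldane`` adds 0.5 to all four cells. A table with
    a == 0 is never a signal under either mode.
    """

    mode: str = "undefined"

    def __post_init__(self) -> None:
        if self.mode not in ("undefined", "haldane"):
            raise ValueError(f"unknown zero-cell mode {self.mode!r}")

    def cells(self, t: ContingencyTable) -> tuple[float, float, float, float] | None:
        """Effective cell values, or None when the row is not computable."""
        if t.a == 0:
            return None
        if min(t.b, t.c, t.d) == 0:
            if self.mode == "undefined":
                return None
            return (t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5)
        return (float(t.a), float(t.b), float(t.c), float(t.d))


@dataclass(frozen=True, slots=True)
class SignalStats:
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    ebgm05: float
    computable: bool = True

    @classmethod
    def not_computable(cls) -> "SignalStats":
        nan = float("nan")
        return cls(nan, nan, nan, nan, nan, nan, nan, nan, nan, computable=False)


@dataclass(frozen=True, slots=True)
class SignalDecision:
    pass_ror: bool
    pass_prr: bool
    pass_bcpnn: bool
    pass_mgps: bool
    significant: bool
    unexpected: bool | None = None


def _wald_se(a: float, b: float, c: float, d: float) -> float:
    return math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)


def compute_ror(
    t: ContingencyTable, policy: ZeroCellPolicy = ZeroCellPolicy()
) -> tuple[float, float, float]:
    """Reporting odds ratio with its 95% Wald CI; NaNs when not computable."""
    cells = policy.cells(t)
    if cells is None:
        return (float("nan"),) * 3
    a, b, c, d = cells
    ror = (a * d) / (b * c)
    half = _Z * _wald_se(a, b, c, d)
    return ror, math.exp(math.log(ror) - half), math.exp(math.log(ror) + half)


def compute_prr_chi2(
    t: ContingencyTable, policy: ZeroCellPolicy = ZeroCellPolicy()
) -> tuple[float, float]:
    """Proportional reporting ratio and Pearson chi-square (no continuity
    correction; the Haldane policy acts on the cells only)."""
    cells = policy.cells(t)
    if cells is None:
        return (float("nan"),) * 2
    a, b, c, d = cells
    n = a + b + c + d
    prr = a * (c + d) / (c * (a + b))
    chi2 = (a * d - b * c) ** 2 * n / ((a + b) * (c + d) * (a + c) * (b + d))
    return prr, chi2


def _bate_ic_variance(a: float, b: float, c: float, d: float) -> float:
    # Moment approximation of the IC posterior variance (Bate et al. 1998),
    # with prior hyperparameters alpha1 = beta1 = gamma11 = 1 (and hence
    # alpha = beta = 2, gamma tuned so the prior IC expectation is 0).
    n = a + b + c + d
    alpha1 = beta1 = gamma11 = 1.0
    alpha = beta = 2.0
    gamma = gamma11 * (n + alpha) * (n + beta) / ((a + b + alpha1) * (a + c + beta1))
    v = (
        (n - a + gamma - gamma11) / ((a + gamma11) * (1 + n + gamma))
        + (n - (a + b) + alpha - alpha1) / ((a + b + alpha1) * (1 + n + alpha))
        + (n - (a + c) + beta - beta1) / ((a + c + beta1) * (1 + n + beta))
    )
    return v / (_LN2 * _LN2)


def compute_bcpnn(
    t: ContingencyTable, policy: ZeroCellPolicy = ZeroCellPolicy()
) -> tuple[float, float]:
    """Simplified information component and its lower credibility bound.

    The point value is the plain log2 observed/expected ratio; the bound is
    IC - 2*sqrt(V) with the moment-approximation variance.
    """
    cells = policy.cells(t)
    if cells is None:
        return (float("nan"),) * 2
    a, b, c, d = cells
    n = a + b + c + d
    ic = math.log2(a * n / ((a + b) * (a + c)))
    ic025 = ic - 2.0 * math.sqrt(_bate_ic_variance(a, b, c, d))
    return ic, ic025


def compute_ebgm(
    t: ContingencyTable, policy: ZeroCellPolicy = ZeroCellPolicy()
) -> tuple[float, float]:
    """Simplified EBGM (observed/expected, no shrinkage) and its lower
    log-normal 95% bound."""
    cells = policy.cells(t)
    if cells is None:
        return (float("nan"),) * 2
    a, b, c, d = cells
    n = a + b + c + d
    ebgm = a * n / ((a + b) * (a + c))
    ebgm05 = math.exp(math.log(ebgm) - _Z * _wald_se(a, b, c, d))
    return ebgm, ebgm05


def compute_all(
    t: ContingencyTable, policy: ZeroCellPolicy = ZeroCellPolicy()
) -> SignalStats:
    if policy.cells(t) is None:
        return SignalStats.not_computable()
    ror, lo, hi = compute_ror(t, policy)
    prr, chi2 = compute_prr_chi2(t, policy)
    ic, ic025 = compute_bcpnn(t, policy)
    ebgm, ebgm05 = compute_ebgm(t, policy)
    return SignalStats(ror, lo, hi, prr, chi2, ic, ic025, ebgm, ebgm05)


def evaluate_criteria(stats: SignalStats, a: int) -> SignalDecision:
    """Apply the four screening criteria; a not-computable row fails all."""
    if not stats.computable:
        return SignalDecision(False, False, False, False, False)
    pass_ror = bool(stats.ror_lo > 1.0 and a >= 3)
    pass_prr = bool(stats.prr >= 2.0 and stats.chi2 >= 4.0 and a >= 3)
    pass_bcpnn = bool(stats.ic025 > 0.0)
    pass_mgps = bool(stats.ebgm05 > 2.0)
    return SignalDecision(
        pass_ror, pass_prr, pass_bcpnn, pass_mgps,
        significant=pass_ror and pass_prr and pass_bcpnn and pass_mgps,
    )


def ic_from_ebgm(ebgm: float) -> float:
    """The simplified-BCPNN identity IC = log2(EBGM)."""
    return math.log2(ebgm)


def ror_from_ci(lo: float, hi: float) -> float:
    """Recover a log-symmetric point estimate as the geometric mean of its
    CI bounds."""
    return math.sqrt(lo * hi)


def _case_terms(case: AnalysisCase, level: Level) -> frozenset[str]:
    return case.pts if level is Level.PT else case.socs


def build_contingency(
    cases: Sequence[AnalysisCase],
    term: str,
    level: Level = Level.PT,
    unit: Unit = Unit.PAIR,
) -> ContingencyTable:
    """Count the 2x2 table for one term over a deduplicated case set.

    ``unit=report``: cells count reports; a report contributes once per
    term even when several of its PTs map to the same SOC.
    ``unit=drug_event_pair``: cells count (report, distinct term) pairs, so
    N is the total number of pairs at the chosen level.
    """
    key = norm_text(term)
    if not key:
        raise ValueError("empty term")
    a = c = 0
    target_pairs = nontarget_pairs = 0
    n_target = n_nontarget = 0
    for case in cases:
        terms = _case_terms(case, level)
        has = key in terms
        if case.is_target:
            n_target += 1
            target_pairs += len(terms)
            a += has
        else:
            n_nontarget += 1
            nontarget_pairs += len(terms)
            c += has
    if unit is Unit.REPORT:
        b, d = n_target - a, n_nontarget - c
    else:
        b, d = target_pairs - a, nontarget_pairs - c
    return ContingencyTable(a=a, b=b, c=c, d=d, unit=unit, level=level, term=key)


def _stats_arrays(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray, policy: ZeroCellPolicy
) -> dict[str, np.ndarray]:
    """Vectorized statistics for parallel cell arrays (float output)."""
    a = a.astype(float).copy()
    b = b.astype(float).copy()
    c = c.astype(float).copy()
    d = d.astype(float).copy()
    zero = np.minimum(np.minimum(b, c), d) == 0
    not_comp = a == 0
    if policy.mode == "haldane":
        for arr in (a, b, c, d):
            arr[zero] += 0.5
    else:
        not_comp |= zero
    ok = ~not_comp
    out = {k: np.full(a.shape, np.nan) for k in
           ("ror", "ror_lo", "ror_hi", "prr", "chi2", "ic", "ic025", "ebgm", "ebgm05")}
    if not ok.any():
        out["computable"] = ok
        return out
    aa, bb, cc, dd = a[ok], b[ok], c[ok], d[ok]
    n = aa + bb + cc + dd
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ror = aa * dd / (bb * cc)
    out["ror"][ok] = ror
    out["ror_lo"][ok] = np.exp(np.log(ror) - _Z * se)
    out["ror_hi"][ok] = np.exp(np.log(ror) + _Z * se)
    out["prr"][ok] = aa * (cc + dd) / (cc * (aa + bb))
    out["chi2"][ok] = (aa * dd - bb * cc) ** 2 * n / ((aa + bb) * (cc + dd) * (aa + cc) * (bb + dd))
    ebgm = aa * n / ((aa + bb) * (aa + cc))
    ic = np.log2(ebgm)
    gamma = (n + 2.0) * (n + 2.0) / ((aa + bb + 1.0) * (aa + cc + 1.0))
    v = (
        (n - aa + gamma - 1.0) / ((aa + 1.0) * (1.0 + n + gamma))
        + (n - aa - bb + 1.0) / ((aa + bb + 1.0) * (3.0 + n))
        + (n - aa - cc + 1.0) / ((aa + cc + 1.0) * (3.0 + n))
    ) / (_LN2 * _LN2)
    out["ic"][ok] = ic
    out["ic025"][ok] = ic - 2.0 * np.sqrt(v)
    out["ebgm"][ok] = ebgm
    out["ebgm05"][ok] = np.exp(np.log(ebgm) - _Z * se)
    out["computable"] = ok
    return out


def screen_signals(
    cases: Sequence[AnalysisCase],
    level: Level = Level.PT,
    unit: Unit = Unit.PAIR,
    policy: ZeroCellPolicy = ZeroCellPolicy(),
    exclusions: Iterable[str] | None = None,
    label_pts: Iterable[str] | None = None,
    meddra: MeddraMap | None = None,
    sort_by: str = "a",
) -> pd.DataFrame:
    """One row of statistics and criteria per observed term at ``level``.

    ``exclusions`` (PT or SOC names) removes matching rows before the
    significant-signal accounting; ``label_pts`` drives the unexpected
    flag via :func:`flag_unexpected`. Sortable by report count ("a") or
    association strength ("ebgm"), descending.
    """
    if not cases:
        raise ValueError("empty case collection")
    if sort_by not in ("a", "ebgm"):
        raise ValueError("sort_by must be 'a' or 'ebgm'")

    from collections import Counter

    count_t: Counter = Counter()
    count_o: Counter = Counter()
    target_pairs = nontarget_pairs = 0
    n_target = n_nontarget = 0
    for case in cases:
        terms = _case_terms(case, level)
        if case.is_target:
            n_target += 1
            target_pairs += len(terms)
            count_t.update(terms)
        else:
            n_nontarget += 1
            nontarget_pairs += len(terms)
            count_o.update(terms)

    terms = sorted(set(count_t) | set(count_o))
    a = np.array([count_t.get(t, 0) for t in terms], dtype=np.int64)
    c = np.array([count_o.get(t, 0) for t in terms], dtype=np.int64)
    if unit is Unit.REPORT:
        b = n_target - a
        d = n_nontarget - c
    else:
        b = target_pairs - a
        d = nontarget_pairs - c

    stats = _stats_arrays(a, b, c, d, policy)
    socs: list[str | None]
    if level is Level.SOC:
        socs = list(terms)
    elif meddra is not None:
        socs = [meddra.soc_of(t) for t in terms]
    else:
        socs = [None] * len(terms)

    df = pd.DataFrame({
        "level": level.value,
        "term": terms,
        "soc": socs,
        "a": a, "b": b, "c": c, "d": d,
        **{k: stats[k] for k in
           ("ror", "ror_lo", "ror_hi", "prr", "chi2", "ic", "ic025", "ebgm", "ebgm05")},
    })
    comp = stats["computable"]
    df["pass_ror"] = comp & (df["ror_lo"].to_numpy() > 1.0) & (a >= 3)
    df["pass_prr"] = comp & (df["prr"].to_numpy() >= 2.0) & (df["chi2"].to_numpy() >= 4.0) & (a >= 3)
    df["pass_bcpnn"] = comp & (df["ic025"].to_numpy() > 0.0)
    df["pass_mgps"] = comp & (df["ebgm05"].to_numpy() > 2.0)
    df["significant"] = df.pass_ror & df.pass_prr & df.pass_bcpnn & df.pass_mgps

    if exclusions is not None:
        excl = {norm_text(x) for x in exclusions}
        keep = ~(
            df["term"].map(norm_text).isin(excl)
            | df["soc"].map(lambda s: norm_text(s) if s else "").isin(excl)
        )
        df = df.loc[keep].reset_index(drop=True)

    df = flag_unexpected(df, label_pts)
    ascending = False
    df = df.sort_values(sort_by, ascending=ascending, kind="mergesort").reset_index(drop=True)
    return df


def flag_unexpected(
    signals: pd.DataFrame, label_pts: Iterable[str] | None
) -> pd.DataFrame:
    """Mark significant terms absent from the label-documented PT list.

    With no list supplied the flag is undetermined (NA) for significant
    rows; non-significant rows are always False.
    """
    df = signals.copy()
    if label_pts is None:
        df["unexpected"] = df["significant"].map(lambda s: pd.NA if s else False)
        return df
    labelled = {norm_text(p) for p in label_pts}
    in_label = df["term"].map(norm_text).isin(labelled)
    df["unexpected"] = df["significant"] & ~in_label
    return df


def reconstruct_cells(
    a: float, ror: float, prr: float, ebgm: float,
    x0: tuple[float, float, float] = (1e4, 1e5, 1e7),
) -> tuple[float, float, float]:
    """Solve the three point-estimate equations for the cells (b, c, d).

    Given a and the ROR, PRR, and simplified EBGM point estimates, finds
    positive (b, c, d) satisfying ROR = ad/(bc), PRR = a(c+d)/(c(a+b)) and
    EBGM = aN/((a+b)(a+c)) by root finding in log space.
    """
    def residuals(x: np.ndarray) -> list[float]:
        b, c, d = np.exp(x)
        n = a + b + c + d
        return [
            math.log(a * d / (b * c) / ror),
            math.log(a * (c + d) / (c * (a + b)) / prr),
            math.log(a * n / ((a + b) * (a + c)) / ebgm),
        ]

    sol = optimize.root(residuals, np.log(np.asarray(x0, dtype=float)), method="hybr")
    if not sol.success:
        raise RuntimeError(f"cell reconstruction did not converge: {sol.message}")
    b, c, d = (float(v) for v in np.exp(sol.x))
    return b, c, d
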