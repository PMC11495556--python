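import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from faersig.disprop import (
    ContingencyTable,
    Level,
    Unit,
    ZeroCellPolicy,
    build_contingency,
    compute_all,
    compute_bcpnn,
    compute_ebgm,
    compute_prr_chi2,
    compute_ror,
    evaluate_criteria,
    flag_unexpected,
    ic_from_ebgm,
    reconstruct_cells,
    ror_from_ci,
    screen_signals,
)

TOY = ContingencyTable(10, 90, 100, 9900)
UNDEF = ZeroCellPolicy("undefined")
HALDANE = ZeroCellPolicy("haldane")

cells = st.integers(min_value=1, max_value=10_000)


class TestComputeRor:
    def test_point_estimate(self):
        ror, _, _ = compute_ror(TOY)
        assert ror == pytest.approx(11.0)

    def test_ci_bounds_frozen_oracle(self):
        # independent evaluation of exp(ln ROR -+ 1.96*sqrt(1/a+1/b+1/c+1/d))
        _, lo, hi = compute_ror(TOY)
        assert lo == pytest.approx(5.559515, abs=1e-5)
        assert hi == pytest.approx(21.764489, abs=1e-5)

    def test_symmetric_table(self):
        ror, lo, hi = compute_ror(ContingencyTable(5, 5, 5, 5))
        assert ror == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_zero_cell_undefined(self):
        ror, lo, hi = compute_ror(ContingencyTable(3, 0, 5, 100), UNDEF)
        assert math.isnan(ror) and math.isnan(lo) and math.isnan(hi)

    def test_zero_cell_haldane(self):
        ror, lo, hi = compute_ror(ContingencyTable(3, 0, 5, 100), HALDANE)
        assert ror == pytest.approx(3.5 * 100.5 / (0.5 * 5.5))
        assert math.isfinite(lo) and math.isfinite(hi)

    def test_a_zero_never_computable(self):
        stats = compute_all(ContingencyTable(0, 10, 10, 100), HALDANE)
        assert not stats.computable
        assert not evaluate_criteria(stats, 0).significant

    @given(cells, cells, cells, cells)
    def test_point_is_geometric_mean_of_ci(self, a, b, c, d):
        ror, lo, hi = compute_ror(ContingencyTable(a, b, c, d))
        assert ror_from_ci(lo, hi) == pytest.approx(ror, rel=1e-12)


class TestComputePrrChi2:
    def test_point_estimate(self):
        prr, _ = compute_prr_chi2(TOY)
        assert prr == pytest.approx(10.0)

    def test_chi2_frozen_oracle(self):
        _, chi2 = compute_prr_chi2(TOY)
        assert chi2 == pytest.approx(74.44717, abs=1e-4)

    @given(cells, cells)
    def test_independence_gives_chi2_zero(self, a, k):
        # ad == bc by construction
        t = ContingencyTable(a, a * k, a, a * k)
        prr, chi2 = compute_prr_chi2(t)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert prr == pytest.approx(1.0)


class TestComputeBcpnn:
    def test_ic_simplified_form(self):
        ic, _ = compute_bcpnn(TOY)
        assert ic == pytest.approx(math.log2(9.1818181818), abs=1e-9)
        assert ic == pytest.approx(3.19878, abs=1e-4)

    def test_ic_zero_at_independence(self):
        ic, _ = compute_bcpnn(ContingencyTable(5, 45, 10, 90))
        assert ic == pytest.approx(0.0, abs=1e-12)

    def test_ic025_within_monte_carlo_band(self):
        # Oracle frozen before implementation: 1e6 draws of the simplified
        # IC under a Dirichlet(a+1, b+1, c+1, d+1) posterior (seed 20240901)
        # gave mean 3.22920, sd 0.40316.  The closed-form lower bound must
        # sit inside the oracle's 3-sigma band.
        mc_mean, mc_sd = 3.22920, 0.40316
        ic, ic025 = compute_bcpnn(TOY)
        assert ic025 == pytest.approx(2.243709, abs=1e-5)  # frozen closed form
        assert mc_mean - 3 * mc_sd < ic025 < mc_mean
        assert ic025 < ic


class TestComputeEbgm:
    def test_point_estimate(self):
        ebgm, _ = compute_ebgm(TOY)
        assert ebgm == pytest.approx(9.181818, abs=1e-5)

    def test_ebgm05_frozen_oracle(self):
        _, ebgm05 = compute_ebgm(TOY)
        assert ebgm05 == pytest.approx(4.640587, abs=1e-5)

    def test_independence_gives_one(self):
        ebgm, _ = compute_ebgm(ContingencyTable(5, 45, 10, 90))
        assert ebgm == pytest.approx(1.0)

    @given(cells, cells, cells, cells)
    def test_ic_equals_log2_ebgm(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        ic, _ = compute_bcpnn(t)
        ebgm, _ = compute_ebgm(t)
        assert ic == pytest.approx(ic_from_ebgm(ebgm), rel=1e-12)

    def test_printed_pairs_identity(self):
        # published EBGM/IC pairs obey IC == log2(EBGM) at 2 decimals
        for ebgm, ic in [(69.95, 6.13), (4.80, 2.26), (1167.10, 10.19)]:
            assert round(ic_from_ebgm(ebgm), 2) == ic


class TestEvaluateCriteria:
    def test_toy_table_decision(self):
        stats = compute_all(TOY)
        decision = evaluate_criteria(stats, TOY.a)
        assert decision.pass_ror and decision.pass_prr and decision.pass_mgps

    def test_case_count_rule(self):
        stats = compute_all(ContingencyTable(2, 1, 1, 10_000))
        decision = evaluate_criteria(stats, 2)
        assert not decision.pass_ror and not decision.pass_prr
        assert not decision.significant

    def test_independence_not_significant(self):
        stats = compute_all(ContingencyTable(5, 45, 10, 90))
        assert not evaluate_criteria(stats, 5).significant

    def test_significant_is_conjunction(self):
        stats = compute_all(TOY)
        d = evaluate_criteria(stats, TOY.a)
        assert d.significant == (d.pass_ror and d.pass_prr and d.pass_bcpnn and d.pass_mgps)


class TestStructuralProperties:
    @given(cells, cells, cells, cells)
    def test_ror_vs_prr_ordering(self, a, b, c, d):
        t = ContingencyTable(a, b, c, d)
        ror, _, _ = compute_ror(t)
        prr, _ = compute_prr_chi2(t)
        if a * d > b * c:
            assert ror > prr
        elif a * d < b * c:
            assert ror < prr
        else:
            assert ror == pytest.approx(prr)

    @given(st.integers(1, 100), cells, cells, cells)
    @settings(max_examples=50)
    def test_ror_prr_monotone_in_a(self, a, b, c, d):
        # ROR and PRR increase strictly in a for any fixed b, c, d
        t1 = ContingencyTable(a, b, c, d)
        t2 = ContingencyTable(a + 1, b, c, d)
        assert compute_ror(t2)[0] > compute_ror(t1)[0]
        assert compute_prr_chi2(t2)[0] > compute_prr_chi2(t1)[0]

    @given(st.integers(1, 100), st.integers(1000, 10_000),
           st.integers(1000, 10_000), st.integers(1000, 10_000))
    @settings(max_examples=50)
    def test_ic_ebgm_monotone_in_sparse_regime(self, a, b, c, d):
        # the observed/expected ratio is only monotone in a when the margins
        # dominate the cell (the realistic sparse-reporting regime); e.g.
        # (1,1,1,5) -> (2,1,1,5) leaves EBGM unchanged at 2.0
        t1 = ContingencyTable(a, b, c, d)
        t2 = ContingencyTable(a + 1, b, c, d)
        assert compute_bcpnn(t2)[0] > compute_bcpnn(t1)[0]
        assert compute_ebgm(t2)[0] > compute_ebgm(t1)[0]


class TestBuildContingency:
    def test_report_unit_hand_enumeration(self, contingency_cases):
        t = build_contingency(contingency_cases, "P1", Level.PT, Unit.REPORT)
        assert (t.a, t.b, t.c, t.d) == (2, 0, 1, 2)

    def test_pair_unit_hand_enumeration(self, contingency_cases):
        t = build_contingency(contingency_cases, "P1", Level.PT, Unit.PAIR)
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 2)
        assert t.n == 6

    def test_absent_term(self, contingency_cases):
        t = build_contingency(contingency_cases, "P99", Level.PT, Unit.REPORT)
        assert t.a == 0
        assert t.b == 2  # all target reports

    def test_soc_level_counts_once_per_report(self, contingency_cases):
        # R1 has P1,P2 -> SOC_A,SOC_B; R3,R5 contribute SOC_A once each
        t = build_contingency(contingency_cases, "SOC_A", Level.SOC, Unit.REPORT)
        assert t.a == 2 and t.c == 2


class TestScreenSignals:
    def test_one_row_per_term(self, contingency_cases):
        df = screen_signals(contingency_cases, level=Level.PT, unit=Unit.PAIR)
        assert sorted(df["term"]) == ["P1", "P2", "P3"]

    def test_matches_scalar_path(self, contingency_cases):
        df = screen_signals(contingency_cases, level=Level.PT, unit=Unit.PAIR)
        for _, row in df.iterrows():
            t = build_contingency(contingency_cases, row["term"], Level.PT, Unit.PAIR)
            assert (t.a, t.b, t.c, t.d) == (row.a, row.b, row.c, row.d)
            stats = compute_all(t)
            if stats.computable:
                assert row["ror"] == pytest.approx(stats.ror, rel=1e-12)
                assert row["ic025"] == pytest.approx(stats.ic025, rel=1e-12)

    def test_exclusion_by_soc(self, contingency_cases, meddra_map):
        df = screen_signals(contingency_cases, level=Level.PT, unit=Unit.PAIR,
                            meddra=meddra_map, exclusions=["SOC_B"])
        assert "P2" not in set(df["term"])
        assert {"P1", "P3"} <= set(df["term"])

    def test_unit_toggle_changes_counts(self, contingency_cases):
        rep = screen_signals(contingency_cases, level=Level.PT, unit=Unit.REPORT)
        pair = screen_signals(contingency_cases, level=Level.PT, unit=Unit.PAIR)
        p1_rep = rep[rep.term == "P1"].iloc[0]
        p1_pair = pair[pair.term == "P1"].iloc[0]
        assert (p1_rep.a, p1_rep.b, p1_rep.c, p1_rep.d) == (2, 0, 1, 2)
        assert (p1_pair.a, p1_pair.b, p1_pair.c, p1_pair.d) == (2, 1, 1, 2)

    def test_pair_unit_conserves_counts(self, contingency_cases):
        df = screen_signals(contingency_cases, level=Level.PT, unit=Unit.PAIR)
        total_target_pairs = sum(len(c.pts) for c in contingency_cases if c.is_target)
        assert df["a"].sum() == total_target_pairs

    def test_sort_by_ebgm(self, contingency_cases):
        df = screen_signals(contingency_cases, level=Level.PT, unit=Unit.PAIR,
                            policy=ZeroCellPolicy("haldane"), sort_by="ebgm")
        vals = df["ebgm"].to_numpy()
        assert all(x >= y for x, y in zip(vals, vals[1:]) if not (np.isnan(x) or np.isnan(y)))


class TestFlagUnexpected:
    def _signals(self, contingency_cases):
        return screen_signals(contingency_cases, level=Level.PT, unit=Unit.PAIR,
                              policy=ZeroCellPolicy("haldane"))

    def test_no_list_gives_undetermined(self, contingency_cases):
        df = self._signals(contingency_cases)
        import pandas as pd
        sig = df[df.significant]
        assert all(pd.isna(v) for v in sig["unexpected"])
        assert not df[~df.significant]["unexpected"].any()

    def test_labelled_term_not_unexpected(self, contingency_cases):
        df = flag_unexpected(self._signals(contingency_cases), ["P1", "P2", "P3"])
        assert not df["unexpected"].any()

    def test_unlabelled_significant_is_unexpected(self, contingency_cases):
        base = self._signals(contingency_cases)
        df = flag_unexpected(base, ["Something else"])
        assert (df["unexpected"] == df["significant"]).all()


class TestReconstructCells:
    def test_recovers_known_cells(self):
        a, b, c, d = 716.0, 8000.0, 15000.0, 14_000_000.0
        n = a + b + c + d
        ror = a * d / (b * c)
        prr = a * (c + d) / (c * (a + b))
        ebgm = a * n / ((a + b) * (a + c))
        rb, rc, rd = reconstruct_cells(a, ror, prr, ebgm)
        assert rb == pytest.approx(b, rel=1e-6)
        assert rc == pytest.approx(c, rel=1e-6)
        assert rd == pytest.approx(d, rel=1e-6)
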