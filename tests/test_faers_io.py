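import dataclasses

import pytest
from hypothesis import given, strategies as st

from faersig.faers_io import (
    CaseRecordBundle,
    ParseLog,
    PartialDate,
    age_to_years,
    parse_faers_date,
    read_quarter_tables,
    write_quarter_tables,
)


class TestParseFaersDate:
    def test_full_precision(self):
        assert parse_faers_date("20201215") == PartialDate(2020, 12, 15)
        assert parse_faers_date("20201215").precision == "day"

    def test_month_precision(self):
        assert parse_faers_date("202012") == PartialDate(2020, 12)
        assert parse_faers_date("202012").precision == "month"

    def test_year_precision(self):
        assert parse_faers_date("2020") == PartialDate(2020)

    def test_empty_is_missing(self):
        assert parse_faers_date("") is None
        assert parse_faers_date(None) is None

    @pytest.mark.parametrize("raw", ["20209912", "20200230", "20201332", "2020123", "ABCD1212"])
    def test_invalid_gives_missing_with_warning(self, raw):
        log = ParseLog()
        assert parse_faers_date(raw, log) is None
        assert log.n_warnings == 1

    @given(st.dates(), st.sampled_from(["day", "month", "year"]))
    def test_serialize_parse_roundtrip(self, date, precision):
        if precision == "day":
            pd_ = PartialDate(date.year, date.month, date.day)
        elif precision == "month":
            pd_ = PartialDate(date.year, date.month)
        else:
            pd_ = PartialDate(date.year)
        assert parse_faers_date(pd_.serialize()) == pd_
        # precision preserved, never upgraded
        assert parse_faers_date(pd_.serialize()).precision == precision


class TestAgeToYears:
    @pytest.mark.parametrize("value,unit,expected", [
        (7.5, "DEC", 75.0),
        (18, "MON", 1.5),
        (365.25, "DY", 1.0),
        (70, "YR", 70.0),
        (730.5, "WK", 14.0),
        (8766, "HR", 1.0),
    ])
    def test_conversions(self, value, unit, expected):
        assert age_to_years(value, unit) == pytest.approx(expected)

    def test_missing_unit_defaults_to_years_with_warning(self):
        log = ParseLog()
        assert age_to_years(64, None, log) == 64.0
        assert log.warnings["missing_age_unit"] == 1

    def test_negative_age_raises(self):
        with pytest.raises(ValueError):
            age_to_years(-1, "YR")


def _write(path, lines):
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


@pytest.fixture
def table_paths(tmp_path):
    _write(tmp_path / "demo.txt", [
        "primaryid$caseid$caseversion$fda_dt$event_dt$rept_dt$age$age_cod$sex$reporter_country$occp_cod",
        "101$C1$1$20210101$20201215$202101$70$YR$M$US$CN",
        "102$C2$1$20210301$$2021$8.2$DEC$F$JP$MD",
    ])
    _write(tmp_path / "drug.txt", [
        "primaryid$drug_seq$role_cod$drugname$prod_ai",
        "101$1$PS$ORGOVYX$RELUGOLIX",
        "102$1$PS$DECOY001$",
    ])
    _write(tmp_path / "reac.txt", ["primaryid$pt", "101$Hot flush", "102$Fatigue"])
    _write(tmp_path / "ther.txt", ["primaryid$dsg_drug_seq$start_dt$end_dt",
                                   "101$1$20201201$"])
    _write(tmp_path / "outc.txt", ["primaryid$outc_cod", "101$HO"])
    return {name: tmp_path / f"{name}.txt" for name in
            ("demo", "drug", "reac", "ther", "outc")}


class TestReadQuarterTables:
    def test_basic_parse(self, table_paths):
        bundle, log = read_quarter_tables(table_paths, "2021Q1")
        assert len(bundle.demo) == 2
        assert bundle.demo[0].fda_dt == PartialDate(2021, 1, 1)
        assert bundle.demo[1].fda_dt == PartialDate(2021, 3, 1)
        assert bundle.demo[0].rept_dt.precision == "month"
        assert bundle.demo[1].event_dt is None
        assert bundle.drugs[1].prod_ai is None
        assert log.n_rejected == 0
        bundle.validate()

    def test_bad_role_cod_rejected(self, table_paths, tmp_path):
        _write(tmp_path / "drug.txt", [
            "primaryid$drug_seq$role_cod$drugname$prod_ai",
            "101$1$XX$ORGOVYX$RELUGOLIX",
        ])
        bundle, log = read_quarter_tables(table_paths)
        assert len(bundle.drugs) == 0
        assert log.rejected["drug"] == 1

    def test_missing_column_is_fatal(self, table_paths, tmp_path):
        _write(tmp_path / "reac.txt", ["primaryid$wrong", "101$Hot flush"])
        with pytest.raises(ValueError, match="pt"):
            read_quarter_tables(table_paths)

    def test_orphan_rows_rejected(self, table_paths, tmp_path):
        _write(tmp_path / "outc.txt", ["primaryid$outc_cod", "999$HO"])
        bundle, log = read_quarter_tables(table_paths)
        assert len(bundle.outcs) == 0
        assert log.rejected["outc"] == 1

    def test_unreadable_date_kept_with_warning(self, table_paths, tmp_path):
        _write(tmp_path / "demo.txt", [
            "primaryid$caseid$caseversion$fda_dt$event_dt$rept_dt$age$age_cod$sex$reporter_country$occp_cod",
            "101$C1$1$20210101$20209912$$bad$YR$M$US$CN",
        ])
        bundle, log = read_quarter_tables(table_paths)
        assert len(bundle.demo) == 1
        assert bundle.demo[0].event_dt is None
        assert bundle.demo[0].age_value is None
        assert log.warnings["bad_date"] == 1
        assert log.warnings["bad_age"] == 1

    def test_no_fabricated_records(self, table_paths, tmp_path):
        # data lines == parsed records + rejections, per table
        _write(tmp_path / "drug.txt", [
            "primaryid$drug_seq$role_cod$drugname$prod_ai",
            "101$1$PS$ORGOVYX$RELUGOLIX",
            "101$2$XX$BAD$",
            "999$1$PS$ORPHAN$",
        ])
        bundle, log = read_quarter_tables(table_paths)
        assert len(bundle.drugs) + log.rejected["drug"] == 3


class TestRoundTrip:
    def test_empty_bundle_writes_headers(self, tmp_path):
        paths = write_quarter_tables(CaseRecordBundle(), tmp_path)
        for path in paths.values():
            assert len(path.read_text().splitlines()) == 1

    def test_write_read_identity(self, flow_bundle, tmp_path):
        paths = write_quarter_tables(flow_bundle, tmp_path)
        back, log = read_quarter_tables(paths, flow_bundle.quarter_label)
        assert back == flow_bundle
        assert log.n_rejected == 0

    def test_write_read_write_byte_identical(self, flow_bundle, tmp_path):
        p1 = write_quarter_tables(flow_bundle, tmp_path / "one")
        back, _ = read_quarter_tables(p1, flow_bundle.quarter_label)
        p2 = write_quarter_tables(back, tmp_path / "two")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()


class TestBundleValidate:
    def test_duplicate_primaryid_fails(self, flow_bundle):
        flow_bundle.demo.append(dataclasses.replace(flow_bundle.demo[0]))
        with pytest.raises(ValueError, match="duplicate primaryid"):
            flow_bundle.validate()

    def test_orphan_reac_fails(self, flow_bundle):
        from faersig.faers_io import ReacRecord
        flow_bundle.reacs.append(ReacRecord("999", "Hot flush"))
        with pytest.raises(ValueError, match="missing from demo"):
            flow_bundle.validate()
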