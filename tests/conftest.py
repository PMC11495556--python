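import pytest

from faersig.faers_io import (
    CaseRecordBundle,
    DemoRecord,
    DrugRecord,
    OutcRecord,
    PartialDate,
    ReacRecord,
    TherRecord,
)
from faersig.preprocess import AnalysisCase, MeddraMap

TARGET_NAMES = ["RELUGOLIX", "ORGOVYX"]


@pytest.fixture
def meddra_map():
    return MeddraMap({
        "Hot flush": "Vascular disorders",
        "Fatigue": "General disorders and administration site conditions",
        "Constipation": "Gastrointestinal disorders",
        "P1": "SOC_A",
        "P2": "SOC_B",
        "P3": "SOC_A",
    })


@pytest.fixture
def flow_bundle():
    """Five raw reports: one duplicated case (C1 v1+v2), two target-PS.

    Hand-enumerated flow accounting: 5 reports -> 4 after dedup -> 2
    target primary-suspect.
    """
    d = PartialDate
    demo = [
        DemoRecord("101", "C1", 1, fda_dt=d(2021, 1, 1), event_dt=d(2021, 1, 1),
                   age_value=70, age_unit="YR", sex="M", reporter_country="US",
                   occp_cod="CN"),
        DemoRecord("106", "C1", 2, fda_dt=d(2021, 3, 1), event_dt=d(2021, 2, 1),
                   age_value=70, age_unit="YR", sex="M", reporter_country="US",
                   occp_cod="CN"),
        DemoRecord("102", "C2", 1, fda_dt=d(2021, 5, 10), event_dt=d(2021, 4, 2),
                   age_value=8.2, age_unit="DEC", sex="M", reporter_country="JP",
                   occp_cod="MD"),
        DemoRecord("103", "C3", 1, fda_dt=d(2022, 2, 1), sex="F",
                   reporter_country="US", occp_cod="HP"),
        DemoRecord("104", "C4", 1, fda_dt=d(2022, 7, 1), sex="UNK"),
    ]
    drugs = [
        DrugRecord("101", 1, "PS", "ORGOVYX", "RELUGOLIX"),
        DrugRecord("106", 1, "PS", "ORGOVYX", "RELUGOLIX"),
        DrugRecord("102", 1, "PS", "relugolix", None),
        DrugRecord("103", 1, "C", "RELUGOLIX", "RELUGOLIX"),  # wrong role
        DrugRecord("103", 2, "PS", "OTHERDRUG", None),
        DrugRecord("104", 1, "PS", "DECOY001", "DECOY001"),
    ]
    reacs = [
        ReacRecord("101", "Hot flush"),
        ReacRecord("106", "Hot flush"),
        ReacRecord("106", "Fatigue"),
        ReacRecord("102", "Hot flush"),
        ReacRecord("103", "Constipation"),
        ReacRecord("104", "Qwertyitis"),
    ]
    thers = [
        TherRecord("106", 1, start_dt=d(2021, 1, 1)),
        TherRecord("102", 1, start_dt=d(2021, 2, 1)),
    ]
    outcs = [
        OutcRecord("106", "HO"),
        OutcRecord("106", "DE"),
        OutcRecord("103", "OT"),
    ]
    return CaseRecordBundle(demo=demo, drugs=drugs, reacs=reacs, thers=thers,
                            outcs=outcs, quarter_label="2021Q1")


def make_case(pid, is_target, pts, socs=None, **kw):
    return AnalysisCase(
        primaryid=pid, caseid=f"C{pid}", is_target=is_target,
        pts=frozenset(p.upper() for p in pts),
        socs=frozenset(s.upper() for s in (socs or [])), **kw,
    )


@pytest.fixture
def contingency_cases():
    """Spec'd hand fixture: {R1:X-PS,{P1,P2}; R2:X-PS,{P1}; R3:Y,{P1};
    R4:Y,{P2}; R5:Y,{P3}}."""
    return [
        make_case("R1", True, ["P1", "P2"], ["SOC_A", "SOC_B"]),
        make_case("R2", True, ["P1"], ["SOC_A"]),
        make_case("R3", False, ["P1"], ["SOC_A"]),
        make_case("R4", False, ["P2"], ["SOC_B"]),
        make_case("R5", False, ["P3"], ["SOC_A"]),
    ]
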