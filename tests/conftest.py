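import datetime as dt

import pytest

from pvsignal import DrugEntry, ReportRecord
from pvsignal import study


def make_report(
    rid,
    drugs,
    reactions,
    case_id=None,
    date=dt.date(2020, 6, 1),
    age=50.0,
    sex="F",
    country="US",
):
    """Compact report builder: drugs as (normalized_name, role) pairs."""
    entries = [
        DrugEntry(verbatim_name=name, role=role, normalized_name=name)
        for name, role in drugs
    ]
    return ReportRecord(
        report_id=rid,
        case_id=case_id or f"case-{rid}",
        receipt_date=date,
        age_years=age,
        sex=sex,
        country=country,
        drugs=entries,
        reactions=frozenset(reactions),
    )


@pytest.fixture
def toy_database():
    """Six hand-enumerated reports: two lithium-PS (one with AKI), one
    semaglutide-PS without AKI, three other-drug reports (one with AKI).
    Against the lithium PS-only query and the AKI endpoint the hand count
    gives (a, b, c, d) = (1, 1, 1, 3)."""
    return [
        make_report("r1", [("lithium", "PS")], {"Acute kidney injury"}),
        make_report("r2", [("lithium", "PS")], {"Nausea"}),
        make_report("r3", [("semaglutide", "PS")], {"Headache"}),
        make_report("r4", [("metformin", "PS")], {"Acute kidney injury"}),
        make_report("r5", [("ibuprofen", "PS")], {"Rash"}),
        make_report("r6", [("sertraline", "PS")], {"Dizziness"}),
    ]


@pytest.fixture(scope="session")
def small_study_db():
    """One modest study-shaped synthetic database shared across tests."""
    import pvsignal as pv

    config = study.default_sim_config(n_reports=20_000, seed=11)
    return pv.generate_reports(config)
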