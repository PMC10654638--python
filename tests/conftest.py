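import pytest

from pvsignals import (
    DrugEntry,
    DrugLexicon,
    ReportStore,
    SafetyReport,
    SimulationConfig,
)
from pvsignals.reports import CONCOMITANT, PRIMARY_SUSPECT


@pytest.fixture
def two_drug_lexicon() -> DrugLexicon:
    return DrugLexicon(
        {
            "denosumab": frozenset({"DENOSUMAB", "Xgeva", "Ranmark", "Prolia"}),
            "zoledronic acid": frozenset(
                {"ZOLEDRONIC ACID", "ZOLEDRONATE", "ACLASTA", "RECLAST", "ZOMETA"}
            ),
        }
    )


def make_report(
    isr_id,
    case_id=None,
    version=1,
    drug="denosumab",
    role=PRIMARY_SUSPECT,
    events=(),
    indications=(),
    extra_drugs=(),
    **kwargs,
):
    """Terse single-PS-drug report builder for unit tests."""
    drugs = (DrugEntry(drug, drug, role),) + tuple(extra_drugs)
    return SafetyReport(
        isr_id=isr_id,
        case_id=case_id if case_id is not None else isr_id,
        version=version,
        drugs=drugs,
        events=frozenset(events),
        indications=frozenset(indications),
        year=kwargs.pop("year", 2020),
        **kwargs,
    )


@pytest.fixture
def report_factory():
    return make_report


@pytest.fixture
def small_store() -> ReportStore:
    """Six deduplicated reports over two drugs."""
    reports = [
        make_report(1, drug="denosumab", events=["onj", "back pain"]),
        make_report(2, drug="denosumab", events=["onj"]),
        make_report(3, drug="denosumab", events=["headache"]),
        make_report(4, drug="zoledronic acid", events=["onj"]),
        make_report(5, drug="zoledronic acid", events=["pyrexia"]),
        make_report(6, drug="background", events=[]),
    ]
    return ReportStore.from_reports(reports, deduplicated=True)


@pytest.fixture
def basic_config() -> SimulationConfig:
    return SimulationConfig(
        n_reports=2000,
        drug_shares={"denosumab": 0.3, "zoledronic acid": 0.2},
        event_vocab={"headache": 0.08, "nausea": 0.05},
        indication_vocab={"denosumab": {"osteoporosis": 0.5, "breast cancer": 0.1}},
        planted=[
            {
                "drug": "denosumab",
                "event": "osteonecrosis of jaw",
                "target_ror": 4.0,
                "background_event_prob": 0.05,
            }
        ],
        duplicate_rate=0.2,
        year_weights={2019: 0.4, 2020: 0.6},
        outcome_probs={"death": 0.1, "hospitalization": 0.2},
        seed=42,
    )


@pytest.fixture
def concomitant_role():
    return CONCOMITANT
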