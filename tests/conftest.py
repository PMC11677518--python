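import math

import pytest

import vigisignal as vs
from vigisignal.synth import SynthConfig


@pytest.fixture(scope="session")
def term_maps():
    return vs.default_term_maps()


@pytest.fixture(scope="session")
def demo_db():
    """Small generated database with signals, duplicates and a risk model."""
    return vs.generate_database(vs.demo_config(n_reports=2000, seed=7))


@pytest.fixture(scope="session")
def demo_clean(demo_db, term_maps):
    clean, _ = vs.deduplicate(demo_db)
    return vs.normalize_events(clean, term_maps)


@pytest.fixture()
def tiny_config():
    return SynthConfig(
        n_reports=500,
        drugs=[("drugA", 0.1), ("drugB", 0.05)],
        events=[("EventX", 0.05), ("EventY", 0.02)],
        planted_signals=[("drugA", "EventX", math.log(4))],
        seed=11,
    )


@pytest.fixture()
def fixture_csv(tmp_path):
    """Hand-written three-row line listing with EudraVigilance-style tokens."""
    text = (
        "case_key,reporter_type,region,sex,age_group,seriousness,"
        "suspect_drugs,concomitant_drugs,indications,reactions\n"
        "EV1,Healthcare Professional,EEA,Female,65-85 years,Results in Death,"
        "calcitriol,calcium carbonate,osteoporosis,Hypercalcaemia;Nausea\n"
        "EV2,Non Healthcare Professional,Non EEA,,18-64 years,"
        "Caused/Prolonged Hospitalisation,cholecalciferol,,,"
        "Blood calcium increased\n"
        "EV3,Healthcare Professional,EEA,Male,3-11 years,Not Specified/Unknown,"
        "alfacalcidol;cholecalciferol,,,Rash\n"
    )
    path = tmp_path / "fixture.csv"
    path.write_text(text)
    return path
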