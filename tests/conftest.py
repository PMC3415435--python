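from datetime import date

import pandas as pd
import pytest

import cypddi
from cypddi.synthetic import EMRTables


@pytest.fixture(scope="session")
def small_kb():
    kb, truth = cypddi.generate_knowledge_base(n_drugs=20, seed=7)
    return kb


@pytest.fixture(scope="session")
def labelled_corpus(small_kb):
    corpus, truth = cypddi.generate_abstract_corpus(small_kb, n_pos=40, n_neg=20, seed=11)
    return corpus, truth


def _emr(person_rows, rx_rows, cond_rows) -> EMRTables:
    person = pd.DataFrame(person_rows, columns=["person_id", "sex", "birth_year"])
    rx = pd.DataFrame(rx_rows, columns=["person_id", "drug_name", "start_date"])
    cond = pd.DataFrame(cond_rows, columns=["person_id", "concept_name", "event_date"])
    rx["start_date"] = pd.to_datetime(rx["start_date"], errors="coerce")
    cond["event_date"] = pd.to_datetime(cond["event_date"], errors="coerce")
    return EMRTables(person, rx, cond)


@pytest.fixture()
def five_patient_emr():
    """Hand-built fixture exercising window and group rules for (subA, inhB).

    p1: substrate 10 days before myopathy            -> substrate_alone case
    p2: substrate and inhibitor 5 days before event  -> joint case
    p3: substrate day 0, inhibitor day 45, no event  -> substrate_alone control
    p4: inhibitor only, no event                     -> inhibitor_alone control
    p5: substrate exactly 30 days before myopathy    -> in-window (boundary)
    """
    myo = "Myalgia and myositis"
    return _emr(
        [
            ("p1", "F", 1970), ("p2", "M", 1950), ("p3", "F", 1980),
            ("p4", "M", 1960), ("p5", "F", 1990),
        ],
        [
            ("p1", "subA", "2005-03-01"),
            ("p2", "subA", "2005-06-05"), ("p2", "inhB", "2005-06-05"),
            ("p3", "subA", "2005-01-01"), ("p3", "inhB", "2005-02-15"),  # 45 d apart
            ("p4", "inhB", "2005-07-01"),
            ("p5", "subA", "2005-04-01"),
        ],
        [
            ("p1", myo, "2005-03-11"),   # 10 days after substrate
            ("p2", myo, "2005-06-10"),   # 5 days after both drugs
            ("p5", myo, "2005-05-01"),   # exactly 30 days after substrate
        ],
    )


@pytest.fixture()
def make_emr():
    return _emr


@pytest.fixture(scope="session")
def db_start():
    return date(2004, 1, 1)
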