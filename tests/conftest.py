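import io

import numpy as np
import pandas as pd
import pytest

from daymark import SynthConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 25-patient cohort with the default (signal-bearing) conditions."""
    return simulate_cohort(SynthConfig(n_patients=25, days_per_patient=90, seed=7))


@pytest.fixture()
def questionnaire_csv():
    """Well-formed 3-record questionnaire file (one labeled, two coded)."""
    return io.StringIO(
        "patient_id,date,question,answer,value\n"
        "p1,2020-01-01,Sleep,So-so,\n"
        "p1,2020-01-01,Motivation,,100\n"
        "p2,2020-01-03,Exercise,,50\n"
    )


@pytest.fixture()
def sobriety_csv():
    return io.StringIO(
        "patient_id,date,status,ami\n"
        "p1,2020-01-01,no_alcohol,95\n"
        "p1,2020-01-02,alcohol_detected,40\n"
        "p1,2020-01-02,no_alcohol,50\n"
        "p2,2020-01-03,all_omitted,\n"
    )


def toy_tables(days, answers, statuses, patient="p1"):
    """Build (q_table, s_table) frames directly from per-day dicts/statuses."""
    start = pd.Timestamp("2020-01-01")
    q_rows = [
        (patient, start + pd.Timedelta(days=d), q, v)
        for d, ans in zip(days, answers)
        for q, v in (ans or {}).items()
    ]
    s_rows = [
        (patient, start + pd.Timedelta(days=d), s)
        for d, s in zip(days, statuses)
        if s is not None
    ]
    q = pd.DataFrame(q_rows, columns=["patient_id", "date", "question", "value"])
    s = pd.DataFrame(s_rows, columns=["patient_id", "date", "status"])
    s["ami"] = np.nan
    return q, s
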