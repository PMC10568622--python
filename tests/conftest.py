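import pandas as pd
import pytest

from gtt_ade import SynthConfig, generate_cohort, generate_study_counts_fixture
from gtt_ade.records import validate_cohort

ADMIT = pd.Timestamp("2021-03-01T08:00")


def build_cohort(admissions=None, meds=(), labs=(), events=(), context=()):
    """Assemble a validated cohort from terse row dicts.

    Defaults: one admission ``A1`` (age 70, 10-day stay starting 2021-03-01).
    Child rows default to admission ``A1`` and sensible timestamps; lab units
    are filled from the analyte table.
    """
    from gtt_ade.records import ANALYTE_UNITS

    if admissions is None:
        admissions = [{}]
    adm_rows = []
    for i, a in enumerate(admissions):
        base = {"admission_id": f"A{i + 1}", "age": 70, "sex": "male",
                "admit_ts": ADMIT, "discharge_ts": ADMIT + pd.Timedelta(days=10),
                "length_of_stay": 10, "n_diagnoses": 4, "allergy_history": False,
                "allergy_list": "", "excluded_flags": ""}
        base.update(a)
        adm_rows.append(base)
    med_rows = []
    for m in meds:
        base = {"admission_id": "A1", "drug_name": "atorvastatin",
                "drug_class": "other", "start_ts": ADMIT + pd.Timedelta(hours=2),
                "stop_ts": ADMIT + pd.Timedelta(days=8), "abrupt_stop": False,
                "dose_reduced": False}
        base.update(m)
        med_rows.append(base)
    lab_rows = []
    for lab in labs:
        base = {"admission_id": "A1", "ts": ADMIT + pd.Timedelta(days=2)}
        base.update(lab)
        base.setdefault("unit", ANALYTE_UNITS[base["analyte"]])
        lab_rows.append(base)
    event_rows = []
    for e in events:
        base = {"admission_id": "A1", "ts": ADMIT + pd.Timedelta(days=3),
                "context_flags": ""}
        base.update(e)
        event_rows.append(base)
    ctx_rows = list(context) or [{"admission_id": r["admission_id"],
                                  "comorbidity_flags": "",
                                  "on_parenteral_nutrition": False}
                                 for r in adm_rows]
    frames = {
        "admissions": pd.DataFrame(adm_rows),
        "medications": pd.DataFrame(med_rows, columns=[
            "admission_id", "drug_name", "drug_class", "start_ts", "stop_ts",
            "abrupt_stop", "dose_reduced"]),
        "labs": pd.DataFrame(lab_rows, columns=[
            "admission_id", "analyte", "value", "unit", "ts"]),
        "events": pd.DataFrame(event_rows, columns=[
            "admission_id", "code", "ts", "context_flags"]),
        "context": pd.DataFrame(ctx_rows, columns=[
            "admission_id", "comorbidity_flags", "on_parenteral_nutrition"]),
    }
    return validate_cohort(frames)


@pytest.fixture(scope="session")
def synth_cohort():
    """Mid-size planted cohort shared across tests (seed fixed)."""
    return generate_cohort(SynthConfig(seed=11, n_admissions=100))


@pytest.fixture(scope="session")
def study_counts():
    return generate_study_counts_fixture()
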