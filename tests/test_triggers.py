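"""Trigger engine: registry integrity, per-rule predicates, and the engine's
monotonicity/determinism properties."""

import copy

import pandas as pd
import pytest

from gtt_ade import EngineConfig, evaluate_cohort, evaluate_trigger, load_registry
from gtt_ade.errors import ConfigurationError
from gtt_ade.triggers import TRIGGER_IDS, TriggerDefinition

from conftest import ADMIT, build_cohort

REGISTRY = load_registry()
BY_ID = {d.id: d for d in REGISTRY}


def hits_for(cohort, trigger_id, config=None):
    view = cohort.view("A1")
    return evaluate_trigger(BY_ID[trigger_id], view, config or EngineConfig())


def test_registry_has_all_36_triggers_once():
    ids = [d.id for d in REGISTRY]
    assert sorted(ids) == sorted(TRIGGER_IDS)
    assert len(ids) == 36
    modules = {d.module for d in REGISTRY}
    counts = {m: sum(d.module == m for d in REGISTRY) for m in modules}
    assert counts == {"laboratory": 17, "treatment": 10, "symptom": 8,
                      "intervention": 1}


def test_unknown_trigger_id_rejected():
    with pytest.raises(Exception):
        TriggerDefinition(id="L99", module="laboratory")


def test_low_potassium_requires_hypokalemic_drug_context():
    with_drug = build_cohort(
        labs=[{"analyte": "K", "value": 2.8}],
        meds=[{"drug_name": "hydrochlorothiazide", "drug_class": "hypokalemic"}])
    assert len(hits_for(with_drug, "L1")) == 1
    without_drug = build_cohort(labs=[{"analyte": "K", "value": 2.8}])
    assert hits_for(without_drug, "L1") == []


def test_potassium_boundary_is_strict():
    cohort = build_cohort(
        labs=[{"analyte": "K", "value": 3.0}],
        meds=[{"drug_name": "hydrochlorothiazide", "drug_class": "hypokalemic"}])
    assert hits_for(cohort, "L1") == []


def test_hyperkalemia_low_branch_needs_reduced_egfr():
    base = dict(meds=[{"drug_name": "spironolactone", "drug_class": "hyperkalemic"}])
    plain = build_cohort(labs=[{"analyte": "K", "value": 5.8}], **base)
    assert hits_for(plain, "L2") == []
    with_egfr = build_cohort(labs=[
        {"analyte": "eGFR", "value": 40.0, "ts": ADMIT + pd.Timedelta(days=1)},
        {"analyte": "K", "value": 5.8, "ts": ADMIT + pd.Timedelta(days=2)}], **base)
    assert len(hits_for(with_egfr, "L2")) == 1


def test_hypoglycemia_threshold_conditional_on_diabetes():
    meds = [{"drug_name": "insulin glargine", "drug_class": "hypoglycemic"}]
    labs = [{"analyte": "glucose_random", "value": 3.5}]
    diabetic = build_cohort(meds=meds, labs=labs, context=[
        {"admission_id": "A1", "comorbidity_flags": "diabetes",
         "on_parenteral_nutrition": False}])
    assert len(hits_for(diabetic, "L4")) == 1
    nondiabetic = build_cohort(meds=meds, labs=labs)
    assert hits_for(nondiabetic, "L4") == []


def test_liver_injury_needs_both_enzymes_and_no_exclusion():
    labs_both = [{"analyte": "ALT", "value": 90.0}, {"analyte": "ALP", "value": 320.0}]
    assert len(hits_for(build_cohort(labs=labs_both), "L6")) == 1
    labs_alt_only = [{"analyte": "ALT", "value": 90.0},
                     {"analyte": "ALP", "value": 200.0}]
    assert hits_for(build_cohort(labs=labs_alt_only), "L6") == []
    excluded = build_cohort(labs=labs_both, context=[
        {"admission_id": "A1", "comorbidity_flags": "",
         "on_parenteral_nutrition": True}])
    assert hits_for(excluded, "L6") == []


def test_creatinine_doubling_uses_in_stay_minimum_as_baseline():
    # no admission value: baseline is the in-stay minimum (80), 170 > 2 x 80
    cohort = build_cohort(labs=[
        {"analyte": "creatinine", "value": 80.0, "ts": ADMIT + pd.Timedelta(days=1)},
        {"analyte": "creatinine", "value": 170.0, "ts": ADMIT + pd.Timedelta(days=4)},
    ])
    hits = hits_for(cohort, "L7")
    assert len(hits) == 1 and hits[0].ts == ADMIT + pd.Timedelta(days=4)
    below = build_cohort(labs=[
        {"analyte": "creatinine", "value": 80.0, "ts": ADMIT + pd.Timedelta(days=1)},
        {"analyte": "creatinine", "value": 155.0, "ts": ADMIT + pd.Timedelta(days=4)},
    ])
    assert hits_for(below, "L7") == []


def test_oliguria_requires_sustained_low_urine_output():
    def urine(values_hours):
        return build_cohort(labs=[
            {"analyte": "urine_output_rate", "value": v,
             "ts": ADMIT + pd.Timedelta(hours=h)} for v, h in values_hours])
    sustained = urine([(0.3, 0), (0.4, 8), (0.3, 14)])
    assert len(hits_for(sustained, "L7")) == 1
    interrupted = urine([(0.3, 0), (0.8, 8), (0.3, 14)])
    assert hits_for(interrupted, "L7") == []


def test_tsh_two_sided_with_thyroid_exclusion():
    labs = [{"analyte": "TSH", "value": 0.1}]
    assert len(hits_for(build_cohort(labs=labs), "L10")) == 1
    excluded = build_cohort(labs=labs, context=[
        {"admission_id": "A1", "comorbidity_flags": "thyroid_dysfunction",
         "on_parenteral_nutrition": False}])
    assert hits_for(excluded, "L10") == []


def test_drug_level_thresholds():
    cohort = build_cohort(labs=[{"analyte": "drug_level_digoxin", "value": 2.4}])
    assert len(hits_for(cohort, "L17")) == 1
    at_limit = build_cohort(labs=[{"analyte": "drug_level_digoxin", "value": 2.0}])
    assert hits_for(at_limit, "L17") == []


def test_allergy_rescue_combination_window():
    both = build_cohort(meds=[
        {"drug_name": "dexamethasone", "drug_class": "corticosteroid"},
        {"drug_name": "epinephrine", "start_ts": ADMIT + pd.Timedelta(hours=3)}])
    assert len(hits_for(both, "T4")) == 1
    apart = build_cohort(meds=[
        {"drug_name": "dexamethasone", "drug_class": "corticosteroid"},
        {"drug_name": "epinephrine", "start_ts": ADMIT + pd.Timedelta(days=3)}])
    assert hits_for(apart, "T4") == []
    antihistamine = build_cohort(meds=[{"drug_name": "loratadine"}])
    assert len(hits_for(antihistamine, "T4")) == 1


def test_hemorrhage_trigger_clauses():
    ev = [{"code": "hemorrhage"}]
    anticoag = build_cohort(events=ev, meds=[
        {"drug_name": "warfarin", "drug_class": "anticoagulant"}])
    assert len(hits_for(anticoag, "C7")) == 1
    bare = build_cohort(events=ev)
    assert hits_for(bare, "C7") == []
    ulcer_nsaid = build_cohort(events=ev, meds=[
        {"drug_name": "ibuprofen", "drug_class": "NSAID"}], context=[
        {"admission_id": "A1", "comorbidity_flags": "peptic_ulcer_history",
         "on_parenteral_nutrition": False}])
    assert len(hits_for(ulcer_nsaid, "C7")) == 1
    ppi_covered = build_cohort(events=ev, meds=[
        {"drug_name": "ibuprofen", "drug_class": "NSAID"},
        {"drug_name": "omeprazole", "drug_class": "PPI"}], context=[
        {"admission_id": "A1", "comorbidity_flags": "peptic_ulcer_history",
         "on_parenteral_nutrition": False}])
    assert hits_for(ppi_covered, "C7") == []


def test_dry_cough_needs_acei_and_no_preexisting_cough():
    acei = [{"drug_name": "enalapril", "drug_class": "ACEI"}]
    fires = build_cohort(events=[{"code": "dry_cough"}], meds=acei)
    assert len(hits_for(fires, "C8")) == 1
    preexisting = build_cohort(events=[
        {"code": "dry_cough", "context_flags": "pre_existing_cough"}], meds=acei)
    assert hits_for(preexisting, "C8") == []


def test_abrupt_stop_and_dose_reduction_toggle():
    stopped = build_cohort(meds=[{"drug_name": "metoprolol", "abrupt_stop": True}])
    assert len(hits_for(stopped, "I1")) == 1
    reduced = build_cohort(meds=[{"drug_name": "metoprolol", "dose_reduced": True}])
    assert hits_for(reduced, "I1") == []
    cfg = EngineConfig(i1_include_dose_reduction=True)
    assert len(hits_for(reduced, "I1", cfg)) == 1


def test_drug_context_window_is_configurable():
    # potassium drawn 10 days after the drug stopped: outside a 7-day window
    cohort = build_cohort(
        labs=[{"analyte": "K", "value": 2.8, "ts": ADMIT + pd.Timedelta(days=9, hours=23)}],
        meds=[{"drug_name": "hydrochlorothiazide", "drug_class": "hypokalemic",
               "start_ts": ADMIT, "stop_ts": ADMIT + pd.Timedelta(days=1)}],
        admissions=[{"length_of_stay": 12,
                     "discharge_ts": ADMIT + pd.Timedelta(days=12)}])
    assert hits_for(cohort, "L1") == []
    wide = EngineConfig(drug_context_window_days=14)
    assert len(hits_for(cohort, "L1", wide)) == 1


def test_counting_policy_per_stay_vs_per_occurrence():
    cohort = build_cohort(labs=[
        {"analyte": "uric_acid", "value": 500.0, "ts": ADMIT + pd.Timedelta(days=1)},
        {"analyte": "uric_acid", "value": 520.0, "ts": ADMIT + pd.Timedelta(days=3)}])
    per_stay = hits_for(cohort, "L15")
    assert len(per_stay) == 1
    assert per_stay[0].ts == ADMIT + pd.Timedelta(days=1)
    per_occ = hits_for(cohort, "L15", EngineConfig(counting_policy="per_occurrence"))
    assert len(per_occ) == 2


def test_empty_and_quiet_cohorts_produce_no_hits():
    quiet = build_cohort(labs=[{"analyte": "K", "value": 4.2}],
                         meds=[{"drug_name": "atorvastatin"}])
    hits = evaluate_cohort(quiet, REGISTRY)
    assert len(hits) == 0


def test_missing_analyte_is_no_hit_not_error():
    assert hits_for(build_cohort(), "L16") == []


def test_threshold_monotonicity_under_cutoff_sweep(synth_cohort):
    """Lowering a '<' cut-off (or raising a '>' cut-off) never adds hits."""
    cohort, _ = synth_cohort
    views = list(cohort.views())

    def count(defn):
        return sum(len(evaluate_trigger(defn, v)) for v in views)

    lt = copy.deepcopy(BY_ID["L16"])         # systolic pressure < cutoff
    counts = []
    for cut in (70.0, 85.0, 90.0, 100.0, 120.0):
        lt.params["threshold"] = cut
        counts.append(count(lt))
    assert counts == sorted(counts)
    gt = copy.deepcopy(BY_ID["L15"])         # uric acid > cutoff
    counts = []
    for cut in (300.0, 400.0, 428.0, 500.0, 700.0):
        gt.params["threshold"] = cut
        counts.append(count(gt))
    assert counts == sorted(counts, reverse=True)


def test_exclusion_flag_never_adds_hits(synth_cohort):
    cohort, _ = synth_cohort
    before = evaluate_cohort(cohort, REGISTRY)
    flagged = cohort.context.copy()
    flagged["comorbidity_flags"] = flagged["comorbidity_flags"].apply(
        lambda s: ";".join(sorted(set(filter(None, s.split(";")))
                                  | {"gout_or_hyperuricemia_history",
                                     "thyroid_dysfunction"})))
    import dataclasses
    cohort2 = dataclasses.replace(cohort, context=flagged)
    after = evaluate_cohort(cohort2, REGISTRY)
    before_keys = set(zip(before["admission_id"], before["trigger_id"]))
    after_keys = set(zip(after["admission_id"], after["trigger_id"]))
    assert after_keys <= before_keys


def test_engine_is_deterministic(synth_cohort):
    cohort, _ = synth_cohort
    h1 = evaluate_cohort(cohort, REGISTRY)
    h2 = evaluate_cohort(cohort, REGISTRY)
    pd.testing.assert_frame_equal(h1, h2)


def test_empty_registry_is_configuration_error(synth_cohort):
    cohort, _ = synth_cohort
    with pytest.raises(ConfigurationError):
        evaluate_cohort(cohort, [])
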