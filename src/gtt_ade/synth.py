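"""Seeded synthetic-cohort generator.

Emulates the marginal structure of an elderly-inpatient geriatrics cohort
(ages truncated-normal around 72.6, stays around 9 days, ~18 distinct drugs
per stay, ~30% antibacterial exposure) and *plants* trigger-positive
conditions and adjudicated ADEs with known ground truth, so that every stage
of the screening pipeline — rule engine, adjudication, metrics, risk models —
is testable end to end without any real patient data.

Planting works constructively: for each planted (admission, trigger) pair the
generator emits exactly the laboratory/medication/event rows that satisfy the
rule's predicate, drug-context requirement and exclusion clauses, and records
the pair in the ground truth. Background rows are drawn from "safe" reference
ranges and a marker-free formulary so they can never fire a rule by accident;
with the default zero noise rate, the engine's hit set equals the planted set
exactly (the generator verifies this at generation time). Covariates are
sampled independently — the generator does not model medications x diagnoses
correlation — and the ADE outcome follows a logistic model in the number of
medications with the intercept solved numerically against the target
prevalence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy.optimize import brentq
from scipy.stats import truncnorm

from .adjudication import ADERecord, naranjo_score
from .errors import GenerationError
from .metrics import StudyCounts
from .records import ANALYTE_UNITS, Cohort, validate_cohort
from .triggers import TRIGGER_IDS, EngineConfig, evaluate_cohort, load_registry

# ---------------------------------------------------------------------------
# Reference study counts (the screening totals the generator's defaults and
# the summary-level fixture emulate: 480 admissions, 281 positive triggers,
# 67 detection pairs, 56 ADEs in 51 patients).
# ---------------------------------------------------------------------------

REFERENCE_TRIGGER_COUNTS: dict[str, tuple[int, int]] = {
    "L1": (6, 1), "L2": (3, 0), "L3": (11, 0), "L4": (13, 2), "L5": (4, 1),
    "L6": (12, 3), "L7": (1, 0), "L8": (3, 1), "L9": (4, 0), "L10": (9, 0),
    "L11": (4, 0), "L12": (3, 0), "L13": (1, 0), "L14": (2, 2), "L15": (73, 8),
    "L16": (4, 3), "L17": (1, 1),
    "T1": (0, 0), "T2": (0, 0), "T3": (7, 0), "T4": (8, 7), "T5": (4, 0),
    "T6": (2, 0), "T7": (29, 2), "T8": (0, 0), "T9": (0, 0), "T10": (1, 1),
    "C1": (13, 8), "C2": (1, 0), "C3": (1, 1), "C4": (1, 0), "C5": (0, 0),
    "C6": (15, 0), "C7": (13, 3), "C8": (3, 2),
    "I1": (29, 21),
}

REFERENCE_ONSET_BINS = {"<=5h": 7, "5h-1d": 23, "1-2d": 12, "2-4d": 9,
                        "4-8d": 2, "prior_to_admission": 3}

# Organ-system symptom entries (61 over 56 ADEs; one event may involve
# several body systems).
REFERENCE_ORGAN_ENTRIES = {
    "gastro_intestinal": 17, "metabolic_nutritional": 15, "skin_appendages": 9,
    "cardiovascular_general": 4, "hepatobiliary": 3, "cns_pns": 3,
    "heart_rate_rhythm": 2, "platelet_bleeding_clotting": 2, "autonomic": 2,
    "respiratory": 2, "body_general": 1, "vision": 1,
}

ORGAN_SYMPTOMS = {
    "gastro_intestinal": "nausea/vomiting",
    "metabolic_nutritional": "hypokalemia",
    "skin_appendages": "rash",
    "cardiovascular_general": "hypotension",
    "hepatobiliary": "hepatic function abnormal",
    "cns_pns": "dizziness/headache",
    "heart_rate_rhythm": "palpitation/QT increased",
    "platelet_bleeding_clotting": "epistaxis/coagulation time increased",
    "autonomic": "sweating increased",
    "respiratory": "dry cough",
    "body_general": "general malaise",
    "vision": "vision abnormal",
}


def generate_study_counts_fixture() -> StudyCounts:
    """Summary-level fixture: the reference screening counts packaged so every
    headline rate and percentage is recomputable from counts alone."""
    return StudyCounts(
        n_admissions=480, mean_length_of_stay=8.95,
        trigger_counts=dict(REFERENCE_TRIGGER_COUNTS),
        patients_with_trigger=232, n_ades=56, n_patients_with_ade=51,
        undetected_ades=4, multiplicity={1: 47, 2: 3, 3: 1},
        severity={1: 11, 2: 42, 3: 3}, during_stay=53,
        onset_bins=dict(REFERENCE_ONSET_BINS),
        organ_entries=dict(REFERENCE_ORGAN_ENTRIES),
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _default_plant_rates() -> dict[str, float]:
    return {t: REFERENCE_TRIGGER_COUNTS[t][0] / 480.0 for t in TRIGGER_IDS}


class SynthConfig(BaseModel):
    """Generator parameters; the defaults are the study conditions emulated.

    All distributions are truncated to their stated ranges. Probabilities are
    per admission unless noted.
    """

    n_admissions: int = Field(default=480, ge=1)
    seed: int = 0
    year: int = 2021

    age_mean: float = 72.61
    age_sd: float = 5.94
    age_min: float = 65.0
    age_max: float = 91.0
    los_mean: float = 8.95
    los_sd: float = 4.57
    los_min: float = 2.0
    los_max: float = 27.0
    meds_mean: float = 18.26
    meds_sd: float = 6.42
    meds_min: float = 5.0
    meds_max: float = 40.0
    dx_mean: float = 5.38
    dx_sd: float = 2.80
    dx_min: float = 1.0
    dx_max: float = 19.0

    p_female: float = Field(default=0.4562, ge=0, le=1)
    p_antibacterial: float = Field(default=0.3083, ge=0, le=1)
    antibacterial_hours_mean: float = 53.42
    antibacterial_hours_sd: float = 103.24
    antibacterial_hours_min: float = 3.0
    antibacterial_hours_max: float = 528.0
    p_allergy_history: float = Field(default=0.1438, ge=0, le=1)

    comorbidity_prevalence: dict[str, float] = Field(default_factory=lambda: {
        "diabetes": 0.30, "thyroid_dysfunction": 0.08,
        "gout_or_hyperuricemia_history": 0.10, "dementia_or_parkinson": 0.05,
        "chronic_renal_failure": 0.06, "hepatobiliary_pancreatic_disease": 0.08,
        "primary_muscle_disease": 0.01, "peptic_ulcer_history": 0.05,
    })
    p_parenteral_nutrition: float = Field(default=0.04, ge=0, le=1)

    per_med_log_or: float = 0.087
    ade_prevalence: float = Field(default=0.1062, gt=0, lt=1)
    multiplicity_probs: dict[int, float] = Field(default_factory=lambda: {
        1: 47 / 51, 2: 3 / 51, 3: 1 / 51})
    p_ade_undetected: float = Field(default=4 / 56, ge=0, le=1)
    p_second_link: float = Field(default=67 / 52 - 1.0, ge=0, le=1)
    severity_probs: dict[int, float] = Field(default_factory=lambda: {
        1: 11 / 56, 2: 42 / 56, 3: 3 / 56})
    onset_probs: dict[str, float] = Field(default_factory=lambda: {
        b: c / 56 for b, c in REFERENCE_ONSET_BINS.items()})
    organ_probs: dict[str, float] = Field(default_factory=lambda: {
        o: c / 61 for o, c in REFERENCE_ORGAN_ENTRIES.items()})
    p_extra_organ_entry: float = Field(default=5 / 56, ge=0, le=1)
    p_medication_error: float = Field(default=2 / 56, ge=0, le=1)
    p_definite: float = Field(default=0.2, ge=0, le=1)
    excluded_candidate_rate: float = Field(default=0.03, ge=0, le=1)

    trigger_plant_rates: dict[str, float] = Field(
        default_factory=_default_plant_rates)
    noise_rate: float = Field(default=0.0, ge=0, le=1)
    self_check: bool = True

    def validate_feasible(self):
        for t, r in self.trigger_plant_rates.items():
            if not 0.0 <= r <= 1.0:
                raise GenerationError(f"plant rate for {t} outside [0, 1]: {r}")
        return self


# Background formulary: (name, class) pairs free of treatment-trigger marker
# substrings, so background orders never fire a treatment rule.
BACKGROUND_FORMULARY = [
    ("cefoperazone/sulbactam", "antibacterial"), ("levofloxacin", "antibacterial"),
    ("piperacillin/tazobactam", "antibacterial"), ("ceftriaxone", "antibacterial"),
    ("moxifloxacin", "antibacterial"),
    ("warfarin", "anticoagulant"), ("enoxaparin", "anticoagulant"),
    ("rivaroxaban", "anticoagulant"),
    ("aspirin", "platelet_inhibitor"), ("clopidogrel", "platelet_inhibitor"),
    ("metformin", "hypoglycemic"), ("gliclazide", "hypoglycemic"),
    ("acarbose", "hypoglycemic"), ("insulin glargine", "hypoglycemic"),
    ("furosemide", "diuretic"), ("torasemide", "diuretic"),
    ("hydrochlorothiazide", "hypokalemic"),
    ("spironolactone", "hyperkalemic"), ("indapamide", "hyponatremic"),
    ("enalapril", "ACEI"), ("benazepril", "ACEI"),
    ("omeprazole", "PPI"), ("pantoprazole", "PPI"),
    ("ibuprofen", "NSAID"), ("celecoxib", "NSAID"),
    ("prednisone", "corticosteroid"),
    ("estazolam", "sedative_hypnotic"), ("zolpidem", "sedative_hypnotic"),
    ("diazepam", "benzodiazepine"),
    ("levodopa", "antiparkinson"), ("sertraline", "SSRI"),
    ("iodixanol", "contrast_agent"), ("digoxin", "digoxin_like"),
    ("atorvastatin", "other"), ("rosuvastatin", "other"),
    ("amlodipine", "other"), ("metoprolol", "other"),
    ("isosorbide dinitrate", "other"), ("amiodarone", "other"),
    ("clonidine", "other"), ("valsartan", "other"),
    ("trimetazidine", "other"), ("mecobalamin", "other"),
    ("calcitriol", "other"), ("alfacalcidol", "other"),
    ("folic acid", "other"), ("potassium citrate", "other"),
    ("esmolol", "other"), ("nifedipine", "other"),
]

# Safe background reference ranges per analyte (never cross a trigger
# threshold under the default registry).
_SAFE_RANGES = {
    "K": (3.6, 5.2), "Na": (136.0, 144.0), "ALT": (8.0, 35.0),
    "ALP": (45.0, 120.0), "PT": (9.5, 12.0), "APTT": (26.0, 36.0),
    "INR": (0.9, 1.3), "platelets": (150.0, 320.0), "TSH": (0.5, 4.4),
    "WBC": (4.0, 9.5), "CK": (30.0, 180.0), "hemoglobin": (100.0, 150.0),
    "uric_acid": (150.0, 420.0), "systolic_bp": (95.0, 160.0),
}


@dataclass
class GroundTruth:
    """What the generator planted, for round-trip verification."""

    plants: list = field(default_factory=list)     # {admission_id, trigger_id, kind}
    ades: list = field(default_factory=list)       # included ADERecord objects
    adjudication_records: list = field(default_factory=list)  # incl. excluded
    seed: int = 0

    def plant_set(self) -> set:
        return {(p["admission_id"], p["trigger_id"]) for p in self.plants}

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "plants": self.plants,
            "ades": [{"ade_id": a.ade_id, "admission_id": a.admission_id,
                      "linked_hits": list(a.linked_hits),
                      "organ_entries": [list(e) for e in a.organ_entries],
                      "ctcae_grade": a.ctcae_grade,
                      "naranjo_category": a.naranjo.category,
                      "onset_bin": a.onset_category}
                     for a in self.ades],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# Row builder
# ---------------------------------------------------------------------------

class _Builder:
    """Accumulates child rows; all timestamps floored to minute resolution."""

    def __init__(self):
        self.meds, self.labs, self.events = [], [], []

    def med(self, aid, name, cls, start, stop, abrupt=False, reduced=False):
        self.meds.append({"admission_id": aid, "drug_name": name,
                          "drug_class": cls, "start_ts": start.floor("min"),
                          "stop_ts": stop.floor("min") if stop is not None else pd.NaT,
                          "abrupt_stop": abrupt, "dose_reduced": reduced})

    def lab(self, aid, analyte, value, ts):
        self.labs.append({"admission_id": aid, "analyte": analyte,
                          "value": round(float(value), 3),
                          "unit": ANALYTE_UNITS[analyte], "ts": ts.floor("min")})

    def event(self, aid, code, ts, flags=""):
        self.events.append({"admission_id": aid, "code": code,
                            "ts": ts.floor("min"), "context_flags": flags})


def _tn(rng, mean, sd, lo, hi, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def solve_intercept(config: SynthConfig) -> float:
    """Solve the ADE-model intercept so that the mean event probability under
    the medications distribution equals the target prevalence."""
    m = np.arange(int(config.meds_min), int(config.meds_max) + 1)
    a, b = ((config.meds_min - config.meds_mean) / config.meds_sd,
            (config.meds_max - config.meds_mean) / config.meds_sd)
    cdf = truncnorm.cdf(np.concatenate([[config.meds_min - 0.5], m + 0.5]),
                        a, b, loc=config.meds_mean, scale=config.meds_sd)
    pmf = np.diff(cdf)
    pmf = pmf / pmf.sum()

    def mean_prev(alpha):
        return float(pmf @ (1.0 / (1.0 + np.exp(-(alpha + config.per_med_log_or * m)))) ) \
            - config.ade_prevalence

    return brentq(mean_prev, -20.0, 5.0, xtol=1e-10)


# ---------------------------------------------------------------------------
# Planters: emit exactly the rows that realize one trigger condition.
# Each returns the name of the context/suspect drug it introduced (or None).
# ---------------------------------------------------------------------------

def _mid_ts(rng, adm, min_h=8.0):
    los_h = adm["length_of_stay"] * 24.0
    return adm["admit_ts"] + pd.Timedelta(hours=float(
        rng.uniform(min_h, max(min_h + 1.0, los_h - 4.0))))


def _ctx_med(b, rng, adm, ts, name, cls):
    start = max(adm["admit_ts"],
                ts - pd.Timedelta(days=float(rng.uniform(0.2, 4.0))))
    stop = min(adm["discharge_ts"], start + pd.Timedelta(days=6))
    b.med(adm["admission_id"], name, cls, start, stop)
    return name


def _plant(b, rng, adm, flags, tid):
    """Realize trigger ``tid`` on admission ``adm``; mutates ``flags`` when an
    exclusion clause must be cleared (or a required comorbidity added)."""
    aid = adm["admission_id"]
    t = _mid_ts(rng, adm)
    if tid == "L1":
        b.lab(aid, "K", rng.uniform(2.2, 2.9), t)
        return _ctx_med(b, rng, adm, t, "hydrochlorothiazide", "hypokalemic")
    if tid == "L2":
        b.lab(aid, "K", rng.uniform(6.05, 7.2), t)
        return _ctx_med(b, rng, adm, t, "spironolactone", "hyperkalemic")
    if tid == "L3":
        b.lab(aid, "Na", rng.uniform(120, 129), t)
        return _ctx_med(b, rng, adm, t, "indapamide", "hyponatremic")
    if tid == "L4":
        lo, hi = (3.0, 3.8) if "diabetes" in flags else (2.0, 2.7)
        b.lab(aid, "glucose_random", rng.uniform(lo, hi), t)
        return _ctx_med(b, rng, adm, t, "insulin glargine", "hypoglycemic")
    if tid == "L5":
        if "diabetes" in flags:
            t0 = max(adm["admit_ts"] + pd.Timedelta(hours=1),
                     t - pd.Timedelta(days=1))
            b.lab(aid, "glucose_random", 6.0, t0)
            b.lab(aid, "glucose_random", 6.0 + 3.0 + rng.uniform(1.0, 4.0), t)
        else:
            b.lab(aid, "glucose_fasting", rng.uniform(8.0, 14.0), t)
        return _ctx_med(b, rng, adm, t, "prednisone", "corticosteroid")
    if tid == "L6":
        flags.discard("hepatobiliary_pancreatic_disease")
        b.lab(aid, "ALT", rng.uniform(2.05, 4.0) * 40.0, t)
        b.lab(aid, "ALP", rng.uniform(2.05, 4.0) * 150.0, t)
        return None
    if tid == "L7":
        base = rng.uniform(55, 75)
        b.lab(aid, "creatinine", base, adm["admit_ts"] + pd.Timedelta(hours=2))
        b.lab(aid, "creatinine", base * rng.uniform(2.1, 2.6), t)
        return None
    if tid == "L8":
        b.lab(aid, "PT", rng.uniform(12.5, 20.0), t)
        return None
    if tid == "L9":
        b.lab(aid, "platelets", rng.uniform(10, 45), t)
        return None
    if tid == "L10":
        flags.discard("thyroid_dysfunction")
        v = rng.uniform(5.5, 12.0) if rng.random() < 0.7 else rng.uniform(0.05, 0.25)
        b.lab(aid, "TSH", v, t)
        return None
    if tid == "L11":
        b.lab(aid, "WBC", rng.uniform(1.0, 2.8), t)
        return None
    if tid == "L12":
        flags.discard("primary_muscle_disease")
        b.lab(aid, "CK", rng.uniform(10.1, 15.0) * 200.0, t)
        return None
    if tid == "L13":
        flags.add("chronic_renal_failure")
        b.lab(aid, "hemoglobin", rng.uniform(125, 155), t)
        return _ctx_med(b, rng, adm, t, "recombinant human erythropoietin", "other")
    if tid == "L14":
        b.event(aid, "ecg_abnormal", t)
        return None
    if tid == "L15":
        flags.discard("gout_or_hyperuricemia_history")
        b.lab(aid, "uric_acid", rng.uniform(440, 700), t)
        return None
    if tid == "L16":
        b.lab(aid, "systolic_bp", rng.uniform(70, 88), t)
        return _ctx_med(b, rng, adm, t, "amlodipine", "other")
    if tid == "L17":
        b.lab(aid, "drug_level_digoxin", rng.uniform(2.1, 3.5), t)
        return _ctx_med(b, rng, adm, t, "digoxin", "digoxin_like")
    if tid == "T1":
        return _marker(b, adm, t, "vitamin k1 injection")
    if tid == "T2":
        return _marker(b, adm, t, "protamine sulfate")
    if tid == "T3":
        _marker(b, adm, t, "regular insulin", cls="hypoglycemic")
        _marker(b, adm, t + pd.Timedelta(hours=2), "potassium chloride injection")
        return "regular insulin"
    if tid == "T4":
        if rng.random() < 0.6:
            return _marker(b, adm, t, "loratadine")
        _marker(b, adm, t, "dexamethasone", cls="corticosteroid")
        _marker(b, adm, t + pd.Timedelta(hours=1), "epinephrine")
        return "dexamethasone"
    if tid == "T5":
        return _marker(b, adm, t, "50% glucose injection")
    if tid == "T6":
        t6 = adm["admit_ts"] + pd.Timedelta(hours=float(
            rng.uniform(36.0, max(37.0, adm["length_of_stay"] * 24.0 - 4.0))))
        start = adm["admit_ts"] - pd.Timedelta(hours=float(rng.uniform(38, 40)))
        b.med(aid, "omeprazole", "PPI", start,
              min(adm["discharge_ts"], start + pd.Timedelta(days=7)))
        return _marker(b, adm, t6, "bifidobacterium triple viable")
    if tid == "T7":
        return _marker(b, adm, t, "reduced glutathione")
    if tid == "T8":
        return _marker(b, adm, t, "flumazenil")
    if tid == "T9":
        return _marker(b, adm, t, "nystatin")
    if tid == "T10":
        return _marker(b, adm, t, "lidocaine")
    if tid == "C1":
        b.event(aid, "rash", t)
        return None
    if tid == "C2":
        b.event(aid, "oversedation_fall", t)
        return _ctx_med(b, rng, adm, t, "estazolam", "sedative_hypnotic")
    if tid == "C3":
        b.event(aid, "delirium", t)
        return None
    if tid == "C4":
        b.event(aid, "epilepsy", t)
        return None
    if tid == "C5":
        flags.discard("dementia_or_parkinson")
        b.event(aid, "cognitive_disorder", t)
        return None
    if tid == "C6":
        b.event(aid, "edema", t)
        return None
    if tid == "C7":
        b.event(aid, "hemorrhage", t)
        return _ctx_med(b, rng, adm, t, "warfarin", "anticoagulant")
    if tid == "C8":
        b.event(aid, "dry_cough", t)
        return _ctx_med(b, rng, adm, t, "enalapril", "ACEI")
    if tid == "I1":
        start = max(adm["admit_ts"], t - pd.Timedelta(days=2))
        b.med(aid, "metoprolol", "other", start, t, abrupt=True)
        return "metoprolol"
    raise GenerationError(f"no planter for trigger {tid!r}")


def _marker(b, adm, ts, name, cls="other"):
    stop = min(adm["discharge_ts"], ts + pd.Timedelta(days=1))
    b.med(adm["admission_id"], name, cls, ts, stop)
    return name


#: Analytes whose background series must be withheld when a trigger that
#: manipulates the same analyte's baseline is planted on the admission.
_SUPPRESS = {
    "L4": ("glucose_fasting", "glucose_postprandial", "glucose_random"),
    "L5": ("glucose_fasting", "glucose_postprandial", "glucose_random"),
    "L7": ("creatinine", "eGFR"),
}

_NARANJO_PATTERNS = {
    "definite": ("yes", "yes", "yes", "yes", "no", "no", "yes", "yes", "yes", "yes"),
    "probable": ("yes", "yes", "yes", "unknown", "no", "unknown", "unknown",
                 "yes", "unknown", "yes"),
    "possible": ("unknown", "yes", "unknown", "unknown", "unknown", "unknown",
                 "unknown", "unknown", "unknown", "unknown"),
    "doubtful": ("unknown",) * 10,
}

_ONSET_DELTAS_H = {"<=5h": (0.5, 5.0), "5h-1d": (5.1, 24.0),
                   "1-2d": (24.1, 48.0), "2-4d": (48.1, 96.0),
                   "4-8d": (96.1, 192.0)}


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_cohort(config: SynthConfig | None = None):
    """Generate a schema-valid cohort plus its ground truth.

    Identical configuration and seed give identical output. When
    ``config.self_check`` is on, the engine is run on the generated cohort
    and the hit set is required to equal the planted set (for zero noise the
    check is exact equality; planted conditions are always a subset).
    """
    config = (config or SynthConfig()).validate_feasible()
    rng = np.random.default_rng(config.seed)
    n = config.n_admissions

    ages = np.rint(_tn(rng, config.age_mean, config.age_sd,
                       config.age_min, config.age_max, n)).astype(int)
    los = np.rint(_tn(rng, config.los_mean, config.los_sd,
                      config.los_min, config.los_max, n)).astype(int)
    meds_n = np.rint(_tn(rng, config.meds_mean, config.meds_sd,
                         config.meds_min, config.meds_max, n)).astype(int)
    dx = np.rint(_tn(rng, config.dx_mean, config.dx_sd,
                     config.dx_min, config.dx_max, n)).astype(int)
    female = rng.random(n) < config.p_female
    anti_user = rng.random(n) < config.p_antibacterial
    allergy = rng.random(n) < config.p_allergy_history

    year_start = pd.Timestamp(f"{config.year}-01-01")
    admit_days = rng.integers(0, 365, n)
    admit_minutes = rng.integers(8 * 60, 20 * 60, n)

    admissions, contexts = [], []
    flags_by_aid: dict[str, set] = {}
    for i in range(n):
        aid = f"A{i + 1:04d}"
        admit = year_start + pd.Timedelta(days=int(admit_days[i]),
                                          minutes=int(admit_minutes[i]))
        admissions.append({
            "admission_id": aid, "age": int(ages[i]),
            "sex": "female" if female[i] else "male",
            "admit_ts": admit,
            "discharge_ts": admit + pd.Timedelta(days=int(los[i])),
            "length_of_stay": int(los[i]), "n_diagnoses": int(dx[i]),
            "allergy_history": bool(allergy[i]),
            "allergy_list": "penicillin" if allergy[i] else "",
            "excluded_flags": "",
        })
        flags = {f for f, p in config.comorbidity_prevalence.items()
                 if rng.random() < p}
        flags_by_aid[aid] = flags
        contexts.append({"admission_id": aid,
                         "on_parenteral_nutrition":
                             bool(rng.random() < config.p_parenteral_nutrition)})

    # --- planted trigger conditions -------------------------------------
    plant_sets: dict[str, set] = {a["admission_id"]: set() for a in admissions}
    plants = []
    for adm in admissions:
        aid = adm["admission_id"]
        for tid in TRIGGER_IDS:
            if rng.random() < config.trigger_plant_rates.get(tid, 0.0):
                plant_sets[aid].add(tid)
                plants.append({"admission_id": aid, "trigger_id": tid,
                               "kind": "plant"})
        if config.noise_rate > 0 and rng.random() < config.noise_rate:
            tid = str(rng.choice(TRIGGER_IDS))
            if tid not in plant_sets[aid]:
                plant_sets[aid].add(tid)
                plants.append({"admission_id": aid, "trigger_id": tid,
                               "kind": "noise"})

    # --- ADE outcome model ----------------------------------------------
    alpha = solve_intercept(config)
    p_ade = 1.0 / (1.0 + np.exp(-(alpha + config.per_med_log_or * meds_n)))
    has_ade = rng.random(n) < p_ade

    mult_ks = sorted(config.multiplicity_probs)
    mult_ps = np.array([config.multiplicity_probs[k] for k in mult_ks])
    mult_ps = mult_ps / mult_ps.sum()

    ade_plan = []  # (admission index, n_links decided later)
    for i in range(n):
        if not has_ade[i]:
            continue
        k = int(rng.choice(mult_ks, p=mult_ps))
        for _ in range(k):
            ade_plan.append(i)

    # decide links; force-plant a trigger when an ADE must be detected but
    # nothing was planted on its admission
    link_plan = []
    plantable = [t for t in TRIGGER_IDS
                 if config.trigger_plant_rates.get(t, 0.0) > 0]
    rate_w = np.array([config.trigger_plant_rates[t] for t in plantable])
    rate_w = rate_w / rate_w.sum()
    for i in ade_plan:
        aid = admissions[i]["admission_id"]
        if rng.random() < config.p_ade_undetected:
            link_plan.append((i, ()))
            continue
        n_links = 1 + int(rng.random() < config.p_second_link)
        have = sorted(plant_sets[aid])
        links = []
        for tid in list(rng.permutation(have))[:n_links]:
            links.append(str(tid))
        while len(links) < n_links:
            tid = str(rng.choice(plantable, p=rate_w))
            if tid not in plant_sets[aid]:
                plant_sets[aid].add(tid)
                plants.append({"admission_id": aid, "trigger_id": tid,
                               "kind": "plant"})
            if tid not in links:
                links.append(tid)
            elif len(have) == 0 and n_links > 1:
                continue
        link_plan.append((i, tuple(links)))

    # --- realize rows ----------------------------------------------------
    b = _Builder()
    suspect_by_aid: dict[str, list] = {}
    for adm, ctx_row in zip(admissions, contexts):
        aid = adm["admission_id"]
        flags = flags_by_aid[aid]
        suspects = []
        for tid in sorted(plant_sets[aid]):
            if tid == "L6":  # liver-injury rule excludes parenteral nutrition
                ctx_row["on_parenteral_nutrition"] = False
            name = _plant(b, rng, adm, flags, tid)
            if name:
                suspects.append((tid, name))
        suspect_by_aid[aid] = suspects

    # background medications
    formulary = BACKGROUND_FORMULARY
    anti_names = [f for f in formulary if f[1] == "antibacterial"]
    other_names = [f for f in formulary if f[1] != "antibacterial"]
    for i, adm in enumerate(admissions):
        aid = adm["admission_id"]
        m = int(meds_n[i])
        chosen = []
        if anti_user[i]:
            chosen.append(anti_names[int(rng.integers(len(anti_names)))])
            m -= 1
        idx = rng.choice(len(other_names), size=min(m, len(other_names)),
                         replace=False)
        chosen.extend(other_names[int(j)] for j in idx)
        los_h = adm["length_of_stay"] * 24.0
        for name, cls in chosen:
            start = adm["admit_ts"] + pd.Timedelta(
                hours=float(rng.uniform(0.5, max(1.0, los_h * 0.6))))
            if cls == "antibacterial":
                dur = float(_tn(rng, config.antibacterial_hours_mean,
                                config.antibacterial_hours_sd,
                                config.antibacterial_hours_min,
                                config.antibacterial_hours_max))
                stop = min(adm["discharge_ts"], start + pd.Timedelta(hours=dur))
            else:
                stop = min(adm["discharge_ts"], start + pd.Timedelta(
                    days=float(rng.uniform(1.0, 10.0))))
            b.med(aid, name, cls, start, stop)

    # background labs in safe ranges
    for i, adm in enumerate(admissions):
        aid = adm["admission_id"]
        suppressed = set()
        for tid in plant_sets[aid]:
            suppressed.update(_SUPPRESS.get(tid, ()))
        los_h = adm["length_of_stay"] * 24.0
        panel = ["K", "Na", "ALT", "ALP", "platelets", "WBC", "hemoglobin",
                 "uric_acid", "systolic_bp"]
        extra = ["PT", "APTT", "INR", "TSH", "CK"]
        panel += [a for a in extra if rng.random() < 0.3]
        for analyte in panel:
            if analyte in suppressed:
                continue
            lo, hi = _SAFE_RANGES[analyte]
            for _ in range(int(rng.integers(1, 4))):
                ts = adm["admit_ts"] + pd.Timedelta(
                    hours=float(rng.uniform(1.0, max(2.0, los_h - 2.0))))
                b.lab(aid, analyte, rng.uniform(lo, hi), ts)
        if "creatinine" not in suppressed:
            center = rng.uniform(55, 95)
            for _ in range(int(rng.integers(1, 3))):
                ts = adm["admit_ts"] + pd.Timedelta(
                    hours=float(rng.uniform(1.0, max(2.0, los_h - 2.0))))
                b.lab(aid, "creatinine", center * rng.uniform(0.92, 1.08), ts)
        if "glucose_fasting" not in suppressed:
            # diabetic background glucose kept in a narrow band so it can
            # never exceed the in-stay minimum by the rise margin
            lo, hi = (6.5, 8.0) if "diabetes" in flags_by_aid[aid] else (4.4, 6.8)
            for _ in range(int(rng.integers(1, 3))):
                ts = adm["admit_ts"] + pd.Timedelta(
                    hours=float(rng.uniform(1.0, max(2.0, los_h - 2.0))))
                b.lab(aid, "glucose_fasting", rng.uniform(lo, hi), ts)

    for c, adm in zip(contexts, admissions):
        c["comorbidity_flags"] = ";".join(sorted(flags_by_aid[adm["admission_id"]]))

    frames = {
        "admissions": pd.DataFrame(admissions),
        "medications": pd.DataFrame(
            b.meds, columns=["admission_id", "drug_name", "drug_class",
                             "start_ts", "stop_ts", "abrupt_stop", "dose_reduced"]),
        "labs": pd.DataFrame(
            b.labs, columns=["admission_id", "analyte", "value", "unit", "ts"]),
        "events": pd.DataFrame(
            b.events, columns=["admission_id", "code", "ts", "context_flags"]),
        "context": pd.DataFrame(contexts)[
            ["admission_id", "comorbidity_flags", "on_parenteral_nutrition"]],
    }
    for key in ("medications", "labs", "events"):
        sort_col = "start_ts" if key == "medications" else "ts"
        frames[key] = frames[key].sort_values(
            ["admission_id", sort_col], kind="stable").reset_index(drop=True)
    cohort = validate_cohort(frames)
    if len(cohort.rejects):
        raise GenerationError(
            f"generator emitted {len(cohort.rejects)} invalid rows:\n"
            f"{cohort.rejects.head()}")

    # --- adjudicated ADEs -------------------------------------------------
    sev_ks = sorted(config.severity_probs)
    sev_ps = np.array([config.severity_probs[k] for k in sev_ks])
    sev_ps = sev_ps / sev_ps.sum()
    onset_ks = list(config.onset_probs)
    onset_ps = np.array([config.onset_probs[k] for k in onset_ks])
    onset_ps = onset_ps / onset_ps.sum()
    organ_ks = list(config.organ_probs)
    organ_ps = np.array([config.organ_probs[k] for k in organ_ks])
    organ_ps = organ_ps / organ_ps.sum()

    med_start = {}
    for row in b.meds:
        key = row["admission_id"]
        if key not in med_start or row["start_ts"] < med_start[key][1]:
            med_start[key] = (row["drug_name"], row["start_ts"])

    ades = []
    for k, (i, links) in enumerate(link_plan):
        adm = admissions[i]
        aid = adm["admission_id"]
        bin_ = str(rng.choice(onset_ks, p=onset_ps))
        suspects = suspect_by_aid[aid]
        linked_suspect = next((nm for tid, nm in suspects if tid in links), None)
        if bin_ == "prior_to_admission":
            admin = adm["admit_ts"] - pd.Timedelta(days=float(rng.uniform(2, 10)))
            onset = adm["admit_ts"] - pd.Timedelta(hours=float(rng.uniform(1, 40)))
            suspect = "digoxin"
        else:
            lo_h, hi_h = _ONSET_DELTAS_H[bin_]
            los_h = adm["length_of_stay"] * 24.0
            if lo_h >= los_h - 1:
                bin_ = "5h-1d"
                lo_h, hi_h = _ONSET_DELTAS_H[bin_]
            if linked_suspect is not None:
                suspect = linked_suspect
                admin = next(r["start_ts"] for r in b.meds
                             if r["admission_id"] == aid
                             and r["drug_name"] == suspect)
            else:
                suspect, admin = med_start[aid]
            delta = float(rng.uniform(lo_h, min(hi_h, max(lo_h + 0.5, los_h - 1))))
            onset = admin + pd.Timedelta(hours=delta)
        grade = int(rng.choice(sev_ks, p=sev_ps))
        organ = str(rng.choice(organ_ks, p=organ_ps))
        entries = [(organ, ORGAN_SYMPTOMS[organ])]
        if rng.random() < config.p_extra_organ_entry:
            second = str(rng.choice(organ_ks, p=organ_ps))
            if second != organ:
                entries.append((second, ORGAN_SYMPTOMS[second]))
        category = "definite" if rng.random() < config.p_definite else "probable"
        ades.append(ADERecord(
            ade_id=f"ADE{k + 1:03d}", admission_id=aid,
            suspect_drugs=(suspect,),
            onset_ts=onset, admin_ts=admin, admit_ts=adm["admit_ts"],
            organ_entries=tuple(entries), ctcae_grade=grade,
            naranjo=naranjo_score(_NARANJO_PATTERNS[category]),
            linked_hits=tuple(links),
            occurred_during_stay=bin_ != "prior_to_admission",
            medication_error=bool(rng.random() < config.p_medication_error),
        ))

    # candidate events that the causality filter must drop
    candidates = list(ades)
    n_excl = 0
    for i, adm in enumerate(admissions):
        if rng.random() < config.excluded_candidate_rate:
            n_excl += 1
            aid = adm["admission_id"]
            suspect, admin = med_start[aid]
            category = "possible" if rng.random() < 0.7 else "doubtful"
            candidates.append(ADERecord(
                ade_id=f"CAND{n_excl:03d}", admission_id=aid,
                suspect_drugs=(suspect,),
                onset_ts=admin + pd.Timedelta(hours=10), admin_ts=admin,
                admit_ts=adm["admit_ts"],
                organ_entries=(("gastro_intestinal",
                                ORGAN_SYMPTOMS["gastro_intestinal"]),),
                ctcae_grade=1,
                naranjo=naranjo_score(_NARANJO_PATTERNS[category]),
                linked_hits=(), occurred_during_stay=True,
                medication_error=False))

    truth = GroundTruth(plants=plants, ades=ades,
                        adjudication_records=candidates, seed=config.seed)

    if config.self_check:
        hits = evaluate_cohort(cohort, load_registry(), EngineConfig())
        hit_set = set(zip(hits["admission_id"], hits["trigger_id"]))
        planted = truth.plant_set()
        missing = planted - hit_set
        if missing:
            raise GenerationError(
                f"{len(missing)} planted condition(s) not detected by the "
                f"engine, e.g. {sorted(missing)[:5]}")
        spurious = hit_set - planted
        if spurious:
            raise GenerationError(
                f"{len(spurious)} unplanted hit(s), e.g. {sorted(spurious)[:5]}")

    return cohort, truth
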