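"""Brute-force reference implementation of the 36 trigger predicates.

Written independently of the engine: plain per-row Python loops over dict
records with the screening thresholds spelled out as literals. Used only to
cross-check the engine's hit set on small cohorts; per-stay counting means
set membership of (admission_id, trigger_id) is sufficient.
"""

from __future__ import annotations

import pandas as pd

WINDOW_DAYS = 7.0


def _rows(df, aid):
    return [r._asdict() if hasattr(r, "_asdict") else dict(r)
            for _, r in df.loc[df["admission_id"] == aid].iterrows()]


def _active(meds, ts, classes=None, names=None):
    lo = ts - pd.Timedelta(days=WINDOW_DAYS)
    for m in meds:
        if classes is not None and m["drug_class"] not in classes:
            continue
        if names is not None and not any(
                x.lower() in str(m["drug_name"]).lower() for x in names):
            continue
        if m["start_ts"] <= ts and (pd.isna(m["stop_ts"]) or m["stop_ts"] > lo):
            return True
    return False


def _vals(labs, analyte):
    return sorted(((r["ts"], float(r["value"])) for r in labs
                   if r["analyte"] == analyte), key=lambda x: x[0])


def _named(meds, names):
    return [m for m in meds if any(x.lower() in str(m["drug_name"]).lower()
                                   for x in names)]


def oracle_admission(aid, labs, meds, events, flags, pn):
    """Return the set of trigger ids firing for one admission."""
    fired = set()

    # -- laboratory -------------------------------------------------------
    for ts, v in _vals(labs, "K"):
        if v < 3.0 and _active(meds, ts, classes={"hypokalemic"}):
            fired.add("L1")
    egfr = _vals(labs, "eGFR")
    for ts, v in _vals(labs, "K"):
        cond = v > 6.0
        if not cond and v > 5.5:
            prior = [x for x in egfr if x[0] <= ts]
            cond = bool(prior) and prior[-1][1] < 50.0
        if cond and _active(meds, ts, classes={"hyperkalemic"}):
            fired.add("L2")
    for ts, v in _vals(labs, "Na"):
        if v < 130.0 and _active(meds, ts, classes={"hyponatremic"}):
            fired.add("L3")
    glu_thr = 3.9 if "diabetes" in flags else 2.8
    glucose = (_vals(labs, "glucose_fasting") + _vals(labs, "glucose_postprandial")
               + _vals(labs, "glucose_random"))
    for ts, v in glucose:
        if v < glu_thr and _active(meds, ts, classes={"hypoglycemic"}):
            fired.add("L4")
    l5_classes = {"hypoglycemic", "corticosteroid"}
    if "diabetes" in flags:
        if len(glucose) >= 2:
            floor = min(v for _, v in glucose) + 3.0
            for ts, v in glucose:
                if v > floor and _active(meds, ts, classes=l5_classes):
                    fired.add("L5")
    else:
        for ts, v in _vals(labs, "glucose_fasting"):
            if v >= 7.0 and _active(meds, ts, classes=l5_classes):
                fired.add("L5")
        for ts, v in _vals(labs, "glucose_postprandial"):
            if v >= 7.8 and _active(meds, ts, classes=l5_classes):
                fired.add("L5")
    if not pn and "hepatobiliary_pancreatic_disease" not in flags:
        if any(v >= 2 * 40.0 for _, v in _vals(labs, "ALT")) and \
                any(v >= 2 * 150.0 for _, v in _vals(labs, "ALP")):
            fired.add("L6")
    creat = _vals(labs, "creatinine")
    if len(creat) >= 2:
        base = min(v for _, v in creat)
        if any(v > 2.0 * base for _, v in creat):
            fired.add("L7")
    if len(egfr) >= 2:
        base = max(v for _, v in egfr)
        if any(v < base and v <= 0.75 * base for _, v in egfr):
            fired.add("L7")
    urine = _vals(labs, "urine_output_rate")
    run = []
    for ts, v in urine:
        if v < 0.5:
            run.append(ts)
            if (run[-1] - run[0]).total_seconds() / 3600.0 > 12.0:
                fired.add("L7")
                run = []
        else:
            run = []
    if any(v > 12.1 for _, v in _vals(labs, "PT")) or \
            any(v > 36.5 for _, v in _vals(labs, "APTT")) or \
            any(v > 3.5 for _, v in _vals(labs, "INR")):
        fired.add("L8")
    if any(v < 50.0 for _, v in _vals(labs, "platelets")):
        fired.add("L9")
    if "thyroid_dysfunction" not in flags:
        if any(v >= 5.0 or v < 0.3 for _, v in _vals(labs, "TSH")):
            fired.add("L10")
    if any(v < 3.0 for _, v in _vals(labs, "WBC")):
        fired.add("L11")
    if "primary_muscle_disease" not in flags:
        if any(v > 10.0 * 200.0 for _, v in _vals(labs, "CK")):
            fired.add("L12")
        myalgia = [e for e in events if e["code"] == "myalgia"]
        if myalgia and len(creat) >= 2:
            base = min(v for _, v in creat)
            if any(v >= base + 44.0 for _, v in creat):
                fired.add("L12")
    if "chronic_renal_failure" in flags:
        for ts, v in _vals(labs, "hemoglobin"):
            if v > 120.0 and _active(meds, ts, names=["erythropoietin"]):
                fired.add("L13")
    if any(e["code"] == "ecg_abnormal" for e in events):
        fired.add("L14")
    if "gout_or_hyperuricemia_history" not in flags:
        if any(v > 428.0 for _, v in _vals(labs, "uric_acid")):
            fired.add("L15")
    if any(v < 90.0 for _, v in _vals(labs, "systolic_bp")):
        fired.add("L16")
    for analyte, thr in (("drug_level_theophylline", 20.0),
                         ("drug_level_digoxin", 2.0),
                         ("drug_level_vancomycin", 20.0),
                         ("drug_level_gentamicin", 10.0),
                         ("drug_level_carbamazepine", 13.0)):
        if any(v > thr for _, v in _vals(labs, analyte)):
            fired.add("L17")

    # -- treatments -------------------------------------------------------
    if _named(meds, ["vitamin k", "phytonadione"]):
        fired.add("T1")
    if _named(meds, ["protamine"]):
        fired.add("T2")
    for a in _named(meds, ["regular insulin"]):
        for b in _named(meds, ["potassium chloride", "sodium bicarbonate injection",
                               "glucose injection"]):
            if abs(a["start_ts"] - b["start_ts"]) <= pd.Timedelta(days=1):
                fired.add("T3")
    if _named(meds, ["loratadine", "diphenhydramine", "promethazine",
                     "cetirizine", "calcium gluconate"]):
        fired.add("T4")
    for a in _named(meds, ["dexamethasone", "methylprednisolone", "hydrocortisone"]):
        for b in _named(meds, ["epinephrine", "adrenaline"]):
            if abs(a["start_ts"] - b["start_ts"]) <= pd.Timedelta(days=1):
                fired.add("T4")
    if _named(meds, ["50% glucose"]):
        fired.add("T5")
    for mk in _named(meds, ["bifidobacterium", "probiotic", "oral vancomycin",
                            "oral metronidazole"]):
        for m in meds:
            if m["drug_class"] in {"antibacterial", "PPI"} \
                    and m["start_ts"] <= mk["start_ts"] \
                    and mk["start_ts"] - m["start_ts"] >= pd.Timedelta(days=3):
                fired.add("T6")
    if _named(meds, ["glutathione", "polyene phosphatidylcholine",
                     "magnesium isoglycyrrhizinate", "diammonium glycyrrhizinate"]):
        fired.add("T7")
    if _named(meds, ["flumazenil"]):
        fired.add("T8")
    if _named(meds, ["nystatin", "sodium bicarbonate gargle"]):
        fired.add("T9")
    if _named(meds, ["phenytoin", "atropine", "lidocaine"]):
        fired.add("T10")

    # -- symptoms ---------------------------------------------------------
    def evts(code):
        return [e for e in events if e["code"] == code]

    if evts("rash"):
        fired.add("C1")
    for e in evts("oversedation_fall"):
        if _active(meds, e["ts"], classes={"sedative_hypnotic", "antiparkinson",
                                           "hypoglycemic", "benzodiazepine",
                                           "ACEI", "diuretic"}):
            fired.add("C2")
    if evts("delirium"):
        fired.add("C3")
    if evts("epilepsy"):
        fired.add("C4")
    if evts("cognitive_disorder") and "dementia_or_parkinson" not in flags:
        fired.add("C5")
    if evts("edema"):
        fired.add("C6")
    for e in evts("hemorrhage"):
        if _active(meds, e["ts"], classes={"platelet_inhibitor", "anticoagulant"}):
            fired.add("C7")
        elif "peptic_ulcer_history" in flags or \
                "history_peptic_ulcer" in str(e.get("context_flags", "")):
            if _active(meds, e["ts"], classes={"NSAID", "corticosteroid"}) \
                    and not _active(meds, e["ts"], classes={"PPI"}):
                fired.add("C7")
    for e in evts("dry_cough"):
        if "pre_existing_cough" in str(e.get("context_flags", "")):
            continue
        if _active(meds, e["ts"], classes={"ACEI"}):
            fired.add("C8")

    # -- intervention -----------------------------------------------------
    if any(bool(m["abrupt_stop"]) for m in meds):
        fired.add("I1")

    return fired


def oracle_hits(cohort) -> set:
    """Hit set {(admission_id, trigger_id)} by brute-force re-evaluation."""
    out = set()
    ctx = {r["admission_id"]: r for _, r in cohort.context.iterrows()}
    for _, adm in cohort.admissions.iterrows():
        aid = adm["admission_id"]
        c = ctx.get(aid)
        flags = set(str(c["comorbidity_flags"]).split(";")) if c is not None else set()
        pn = bool(c["on_parenteral_nutrition"]) if c is not None else False
        fired = oracle_admission(
            aid,
            _rows(cohort.labs, aid),
            _rows(cohort.medications, aid),
            _rows(cohort.events, aid),
            flags, pn)
        out.update((aid, t) for t in fired)
    return out
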