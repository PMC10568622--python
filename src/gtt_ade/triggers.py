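"""The 36-rule trigger engine.

A *trigger* is a screening rule — an abnormal laboratory value, a marker
treatment (antidote/rescue drug), a clinical symptom, or a medication-stop
intervention — whose firing flags an admission for focused ADE review. Each
rule couples a predicate over the admission's rows with an optional
*drug-context* requirement (a drug of a named class active within a window
before the observation) and *exclusion clauses* (comorbidities or event
context that explain the abnormality without a drug).

The default registry (``data/triggers.yaml``) defines 17 laboratory rules
(L1-L17), 10 treatment rules (T1-T10), 8 symptom rules (C1-C8) and one
intervention rule (I1). Under the default counting policy an admission
contributes at most one hit per trigger (the earliest occurrence).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Literal

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .errors import ConfigurationError
from .records import AdmissionView, Cohort

TRIGGER_IDS = tuple(
    [f"L{i}" for i in range(1, 18)] + [f"T{i}" for i in range(1, 11)]
    + [f"C{i}" for i in range(1, 9)] + ["I1"]
)

MODULES = ("laboratory", "treatment", "symptom", "intervention")


class TriggerDefinition(BaseModel):
    id: str
    module: Literal["laboratory", "treatment", "symptom", "intervention"]
    interpretation: str = ""
    params: dict = Field(default_factory=dict)
    requires_drug_class: list[str] = Field(default_factory=list)
    requires_drug_name: list[str] = Field(default_factory=list)
    requires_comorbidity: list[str] = Field(default_factory=list)
    exclude_comorbidity: list[str] = Field(default_factory=list)
    exclude_event_context: list[str] = Field(default_factory=list)
    exclude_parenteral_nutrition: bool = False

    @field_validator("id")
    @classmethod
    def _known_id(cls, v):
        if v not in TRIGGER_IDS:
            raise ValueError(f"unknown trigger id {v!r}")
        return v


class EngineConfig(BaseModel):
    """Engine toggles; defaults reproduce the primary trigger list."""

    drug_context_window_days: float = Field(default=7.0, gt=0)
    counting_policy: Literal["per_stay", "per_occurrence"] = "per_stay"
    i1_include_dose_reduction: bool = False


@dataclass(frozen=True)
class TriggerHit:
    admission_id: str
    trigger_id: str
    ts: pd.Timestamp
    evidence: tuple


def default_registry_path() -> Path:
    return Path(str(resources.files("gtt_ade").joinpath("data/triggers.yaml")))


def load_registry(path=None) -> list[TriggerDefinition]:
    """Load a trigger registry from YAML; the shipped default must define all
    36 ids exactly once."""
    path = Path(path) if path is not None else default_registry_path()
    if not path.exists():
        raise ConfigurationError(f"trigger registry not found: {path}")
    raw = yaml.safe_load(path.read_text())
    try:
        defs = [TriggerDefinition(**entry) for entry in raw["triggers"]]
    except Exception as exc:  # malformed params surface at registry load
        raise ConfigurationError(f"malformed trigger registry {path}: {exc}") from exc
    ids = [d.id for d in defs]
    if len(ids) != len(set(ids)):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ConfigurationError(f"duplicate trigger ids in registry: {dup}")
    return defs


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _lab_rows(view: AdmissionView, analyte: str):
    df = view.labs
    return df.loc[df["analyte"] == analyte]


def _lab_ev(row) -> dict:
    return {"table": "labs", "analyte": row["analyte"], "value": float(row["value"]),
            "ts": str(row["ts"])}


def _med_ev(row) -> dict:
    return {"table": "medications", "drug_name": row["drug_name"],
            "drug_class": row["drug_class"], "start_ts": str(row["start_ts"])}


def _event_ev(row) -> dict:
    ev = {"table": "events", "code": row["code"], "ts": str(row["ts"])}
    if "context_flags" in row and row["context_flags"]:
        ev["context_flags"] = str(row["context_flags"])
    return ev


def _active_meds(view: AdmissionView, ts, window_days: float,
                 classes=None, names=None):
    """Medication orders of the given class/name active in the window before
    ``ts``: order interval [start, stop) intersects (ts - window, ts].
    An order with no stop timestamp is treated as ongoing."""
    out = []
    lo = ts - pd.Timedelta(days=window_days)
    for _, m in view.meds.iterrows():
        if classes is not None and m["drug_class"] not in classes:
            continue
        if names is not None and not _name_match(m["drug_name"], names):
            continue
        if m["start_ts"] <= ts and (pd.isna(m["stop_ts"]) or m["stop_ts"] > lo):
            out.append(m)
    return out


def _name_match(drug_name: str, markers) -> bool:
    low = str(drug_name).lower()
    return any(marker.lower() in low for marker in markers)


def _cmp(value: float, op: str, threshold: float) -> bool:
    if op == "lt":
        return value < threshold
    if op == "gt":
        return value > threshold
    if op == "ge":
        return value >= threshold
    if op == "le":
        return value <= threshold
    raise ConfigurationError(f"unknown comparison op {op!r}")


# ---------------------------------------------------------------------------
# Per-trigger candidate generators.
# Each returns a list of (ts, [evidence dicts]) satisfying the rule's core
# predicate; class/name drug-context requirements are enforced by the wrapper.
# ---------------------------------------------------------------------------

def _cand_simple_lab(view, p):
    out = []
    for _, r in _lab_rows(view, p["analyte"]).iterrows():
        if _cmp(float(r["value"]), p["op"], float(p["threshold"])):
            out.append((r["ts"], [_lab_ev(r)]))
    return out


def _cand_L2(view, p):
    out = []
    egfr = _lab_rows(view, "eGFR")
    for _, r in _lab_rows(view, "K").iterrows():
        v = float(r["value"])
        if v > p["threshold"]:
            out.append((r["ts"], [_lab_ev(r)]))
        elif v > p["alt_threshold"]:
            prior = egfr.loc[egfr["ts"] <= r["ts"]]
            if not prior.empty:
                last = prior.iloc[-1]
                if float(last["value"]) < p["egfr_below"]:
                    out.append((r["ts"], [_lab_ev(r), _lab_ev(last)]))
    return out


def _cand_L4(view, p):
    thr = p["threshold_diabetes"] if "diabetes" in view.comorbidities \
        else p["threshold_no_diabetes"]
    out = []
    for analyte in p["analytes"]:
        for _, r in _lab_rows(view, analyte).iterrows():
            if float(r["value"]) < thr:
                out.append((r["ts"], [_lab_ev(r)]))
    return out


_GLUCOSE_ANALYTES = ("glucose_fasting", "glucose_postprandial", "glucose_random")


def _cand_L5(view, p):
    out = []
    if "diabetes" in view.comorbidities:
        rows = view.labs.loc[view.labs["analyte"].isin(_GLUCOSE_ANALYTES)]
        if len(rows) < 2:
            return out
        floor = rows["value"].astype(float).min() + p["diabetes_rise_margin"]
        for _, r in rows.iterrows():
            if float(r["value"]) > floor:
                out.append((r["ts"], [_lab_ev(r)]))
    else:
        for analyte, thr in (("glucose_fasting", p["fasting_ge"]),
                             ("glucose_postprandial", p["postprandial_ge"])):
            for _, r in _lab_rows(view, analyte).iterrows():
                if float(r["value"]) >= thr:
                    out.append((r["ts"], [_lab_ev(r)]))
    return out


def _cand_L6(view, p):
    alt = _lab_rows(view, "ALT")
    alp = _lab_rows(view, "ALP")
    alt_hit = alt.loc[alt["value"].astype(float) >= p["multiple"] * p["alt_uln"]]
    alp_hit = alp.loc[alp["value"].astype(float) >= p["multiple"] * p["alp_uln"]]
    if alt_hit.empty or alp_hit.empty:
        return []
    a, b = alt_hit.iloc[0], alp_hit.iloc[0]
    return [(max(a["ts"], b["ts"]), [_lab_ev(a), _lab_ev(b)])]


def _cand_L7(view, p):
    out = []
    creat = _lab_rows(view, "creatinine")
    if len(creat) >= 2:
        base = creat["value"].astype(float).min()
        for _, r in creat.iterrows():
            if float(r["value"]) > p["creatinine_fold"] * base:
                out.append((r["ts"], [_lab_ev(r),
                                      {"table": "labs", "analyte": "creatinine",
                                       "baseline": base}]))
    egfr = _lab_rows(view, "eGFR")
    if len(egfr) >= 2:
        base = egfr["value"].astype(float).max()
        for _, r in egfr.iterrows():
            v = float(r["value"])
            if v < base and v <= (1.0 - p["egfr_drop_fraction"]) * base:
                out.append((r["ts"], [_lab_ev(r),
                                      {"table": "labs", "analyte": "eGFR",
                                       "baseline": base}]))
    urine = _lab_rows(view, "urine_output_rate")
    if not urine.empty:
        run = []
        for _, r in urine.iterrows():
            if float(r["value"]) < p["urine_rate_below"]:
                run.append(r)
                span = (run[-1]["ts"] - run[0]["ts"]).total_seconds() / 3600.0
                if span > p["urine_duration_hours"]:
                    out.append((run[-1]["ts"], [_lab_ev(x) for x in run]))
                    run = []
            else:
                run = []
    return out


def _cand_L8(view, p):
    out = []
    for analyte, thr in (("PT", p["pt_gt"]), ("APTT", p["aptt_gt"]),
                         ("INR", p["inr_gt"])):
        for _, r in _lab_rows(view, analyte).iterrows():
            if float(r["value"]) > thr:
                out.append((r["ts"], [_lab_ev(r)]))
    return out


def _cand_L10(view, p):
    out = []
    for _, r in _lab_rows(view, "TSH").iterrows():
        v = float(r["value"])
        if v >= p["tsh_ge"] or v < p["tsh_lt"]:
            out.append((r["ts"], [_lab_ev(r)]))
    return out


def _cand_L12(view, p):
    out = []
    for _, r in _lab_rows(view, "CK").iterrows():
        if float(r["value"]) > p["ck_fold"] * p["ck_uln"]:
            out.append((r["ts"], [_lab_ev(r)]))
    myalgia = view.events.loc[view.events["code"].isin(p["myalgia_codes"])]
    creat = _lab_rows(view, "creatinine")
    if not myalgia.empty and len(creat) >= 2:
        base = creat["value"].astype(float).min()
        risen = creat.loc[creat["value"].astype(float) >= base + p["creatinine_rise"]]
        if not risen.empty:
            ev_row = myalgia.iloc[0]
            out.append((ev_row["ts"], [_event_ev(ev_row), _lab_ev(risen.iloc[0])]))
    return out


def _cand_L17(view, p):
    out = []
    for analyte, thr in p["levels"].items():
        for _, r in _lab_rows(view, analyte).iterrows():
            if float(r["value"]) > thr:
                out.append((r["ts"], [_lab_ev(r)]))
    return out


def _cand_events(view, defn):
    codes = defn.params["event_codes"]
    excl = set(defn.exclude_event_context)
    out = []
    for _, r in view.events.iterrows():
        if r["code"] not in codes:
            continue
        flags = set(str(r["context_flags"]).split(";")) if r["context_flags"] else set()
        if flags & excl:
            continue
        out.append((r["ts"], [_event_ev(r)]))
    return out


def _cand_treatment_names(view, names):
    out = []
    for _, m in view.meds.iterrows():
        if _name_match(m["drug_name"], names):
            out.append((m["start_ts"], [_med_ev(m)]))
    return out


def _cand_treatment_combo(view, combo_a, combo_b, within_days):
    out = []
    delta = pd.Timedelta(days=within_days)
    for _, a in view.meds.iterrows():
        if not _name_match(a["drug_name"], combo_a):
            continue
        for _, b in view.meds.iterrows():
            if not _name_match(b["drug_name"], combo_b):
                continue
            if abs(a["start_ts"] - b["start_ts"]) <= delta:
                out.append((max(a["start_ts"], b["start_ts"]),
                            [_med_ev(a), _med_ev(b)]))
    return out


def _cand_T3(view, p):
    return _cand_treatment_combo(view, p["combo_a"], p["combo_b"],
                                 p["combo_within_days"])


def _cand_T4(view, p):
    out = _cand_treatment_names(view, p["names"])
    out += _cand_treatment_combo(view, p["combo_a"], p["combo_b"],
                                 p["combo_within_days"])
    return out


def _cand_T6(view, p):
    out = []
    min_gap = pd.Timedelta(days=p["prior_min_days"])
    for marker_ts, ev in _cand_treatment_names(view, p["names"]):
        for _, m in view.meds.iterrows():
            if m["drug_class"] in p["prior_classes"] \
                    and m["start_ts"] <= marker_ts \
                    and marker_ts - m["start_ts"] >= min_gap:
                out.append((marker_ts, ev + [_med_ev(m)]))
                break
    return out


def _cand_C7(view, defn, cfg: EngineConfig):
    p = defn.params
    out = []
    ulcer_hx = "peptic_ulcer_history" in view.comorbidities
    for ts, ev in _cand_events(view, defn):
        flags = ev[0].get("context_flags", "")
        event_ulcer = "history_peptic_ulcer" in str(flags)
        anti = _active_meds(view, ts, cfg.drug_context_window_days,
                            classes=set(p["antithrombotic_classes"]))
        if anti:
            out.append((ts, ev + [_med_ev(anti[0])]))
            continue
        if ulcer_hx or event_ulcer:
            risk = _active_meds(view, ts, cfg.drug_context_window_days,
                                classes=set(p["ulcer_risk_classes"]))
            ppi = _active_meds(view, ts, cfg.drug_context_window_days,
                               classes={p["ppi_class"]})
            if risk and not ppi:
                out.append((ts, ev + [_med_ev(risk[0])]))
    return out


def _cand_I1(view, p, cfg: EngineConfig):
    include_reduction = p.get("include_dose_reduction", False) \
        or cfg.i1_include_dose_reduction
    out = []
    for _, m in view.meds.iterrows():
        if bool(m["abrupt_stop"]) or (include_reduction and bool(m["dose_reduced"])):
            ts = m["stop_ts"] if not pd.isna(m["stop_ts"]) else m["start_ts"]
            out.append((ts, [_med_ev(m)]))
    return out


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

_SIMPLE_LAB_IDS = {"L1", "L3", "L9", "L11", "L13", "L15", "L16"}


def _candidates(defn: TriggerDefinition, view: AdmissionView,
                cfg: EngineConfig) -> list:
    tid, p = defn.id, defn.params
    if tid in _SIMPLE_LAB_IDS:
        return _cand_simple_lab(view, p)
    if tid == "L2":
        return _cand_L2(view, p)
    if tid == "L4":
        return _cand_L4(view, p)
    if tid == "L5":
        return _cand_L5(view, p)
    if tid == "L6":
        return _cand_L6(view, p)
    if tid == "L7":
        return _cand_L7(view, p)
    if tid == "L8":
        return _cand_L8(view, p)
    if tid == "L10":
        return _cand_L10(view, p)
    if tid == "L12":
        return _cand_L12(view, p)
    if tid == "L14":
        return _cand_events(view, defn)
    if tid == "L17":
        return _cand_L17(view, p)
    if tid == "T3":
        return _cand_T3(view, p)
    if tid == "T4":
        return _cand_T4(view, p)
    if tid == "T6":
        return _cand_T6(view, p)
    if tid.startswith("T"):
        return _cand_treatment_names(view, p["names"])
    if tid == "C7":
        return _cand_C7(view, defn, cfg)
    if tid.startswith("C"):
        return _cand_events(view, defn)
    if tid == "I1":
        return _cand_I1(view, p, cfg)
    raise ConfigurationError(f"no evaluator for trigger {tid!r}")


def evaluate_trigger(defn: TriggerDefinition, view: AdmissionView,
                     config: EngineConfig | None = None) -> list[TriggerHit]:
    """Evaluate one rule on one admission. A hit requires the core predicate,
    the drug-context requirement (if any) near the observation, and the
    absence of every exclusion clause. Deterministic given the slice."""
    cfg = config or EngineConfig()
    if set(defn.exclude_comorbidity) & view.comorbidities:
        return []
    if defn.exclude_parenteral_nutrition and view.on_parenteral_nutrition:
        return []
    if defn.requires_comorbidity and \
            not set(defn.requires_comorbidity) <= view.comorbidities:
        return []
    hits = []
    for ts, evidence in _candidates(defn, view, cfg):
        if defn.requires_drug_class:
            active = _active_meds(view, ts, cfg.drug_context_window_days,
                                  classes=set(defn.requires_drug_class))
            if not active:
                continue
            evidence = evidence + [_med_ev(active[0])]
        if defn.requires_drug_name:
            active = _active_meds(view, ts, cfg.drug_context_window_days,
                                  names=defn.requires_drug_name)
            if not active:
                continue
            evidence = evidence + [_med_ev(active[0])]
        hits.append(TriggerHit(view.admission_id, defn.id, ts, tuple(
            tuple(sorted(e.items())) for e in evidence)))
    hits.sort(key=lambda h: (h.ts, h.evidence))
    if cfg.counting_policy == "per_stay" and hits:
        hits = hits[:1]
    return hits


def evaluate_cohort(cohort: Cohort, registry: list[TriggerDefinition] | None = None,
                    config: EngineConfig | None = None) -> pd.DataFrame:
    """Run every registered rule over every admission.

    Returns the hit table: one row per (admission, trigger) firing with the
    timestamp of the triggering observation and structured evidence, stably
    ordered by (admission_id, trigger_id, ts).
    """
    registry = registry if registry is not None else load_registry()
    if not registry:
        raise ConfigurationError("empty trigger registry")
    cfg = config or EngineConfig()
    rows = []
    for view in cohort.views():
        for defn in registry:
            for hit in evaluate_trigger(defn, view, cfg):
                rows.append({"admission_id": hit.admission_id,
                             "trigger_id": hit.trigger_id, "ts": hit.ts,
                             "evidence": json.dumps(
                                 [dict(e) for e in hit.evidence], default=str)})
    table = pd.DataFrame(rows, columns=["admission_id", "trigger_id", "ts", "evidence"])
    return table.sort_values(["admission_id", "trigger_id", "ts"],
                             kind="stable").reset_index(drop=True)


def trigger_activation_summary(hits: pd.DataFrame,
                               registry: list[TriggerDefinition] | None = None):
    """Per-trigger positive counts plus the number of rules that fired at all."""
    registry = registry if registry is not None else load_registry()
    counts = hits.groupby("trigger_id").size() if len(hits) else pd.Series(dtype=int)
    summary = pd.DataFrame({
        "trigger_id": [d.id for d in registry],
        "module": [d.module for d in registry],
        "positive_count": [int(counts.get(d.id, 0)) for d in registry],
    })
    n_fired = int((summary["positive_count"] > 0).sum())
    return summary, n_fired


def write_hits(hits: pd.DataFrame, path) -> None:
    out = hits.copy()
    out["ts"] = pd.to_datetime(out["ts"]).dt.strftime("%Y-%m-%dT%H:%M")
    out.to_csv(path, index=False)


def read_hits(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df["ts"] = pd.to_datetime(df["ts"])
    return df
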