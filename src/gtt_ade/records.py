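"""Tabular EHR data model: vocabularies, the :class:`Cohort` container, CSV I/O,
row validation and the eligibility filter.

The pipeline consumes five comma-separated files (``admissions.csv``,
``medications.csv``, ``labs.csv``, ``events.csv``, ``context.csv``), UTF-8 with a
mandatory header row. Timestamps are ISO-8601 at minute resolution; all interval
logic downstream uses half-open intervals ``[start, stop)``. Set-valued columns
(allergy list, flags) are semicolon-separated.

Units are fixed per analyte and validated at load; the engine never converts
units, because every screening threshold is stated in a single unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .errors import ReferentialError, SchemaError

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

SEXES = frozenset({"male", "female"})

DRUG_CLASSES = frozenset({
    "antibacterial", "anticoagulant", "hypoglycemic", "diuretic", "ACEI",
    "contrast_agent", "benzodiazepine", "digoxin_like", "PPI", "NSAID",
    "corticosteroid", "hypokalemic", "hyperkalemic", "hyponatremic",
    "sedative_hypnotic", "antiparkinson", "platelet_inhibitor", "SSRI", "other",
})

#: Fixed measurement unit per analyte; thresholds downstream assume these.
ANALYTE_UNITS: Mapping[str, str] = {
    "K": "mmol/L",
    "Na": "mmol/L",
    "glucose_fasting": "mmol/L",
    "glucose_postprandial": "mmol/L",
    "glucose_random": "mmol/L",
    "ALT": "U/L",
    "ALP": "U/L",
    "creatinine": "umol/L",
    "eGFR": "mL/min",
    "PT": "s",
    "APTT": "s",
    "INR": "ratio",
    "platelets": "1e9/L",
    "TSH": "mIU/L",
    "WBC": "1e9/L",
    "CK": "U/L",
    "hemoglobin": "g/L",
    "uric_acid": "umol/L",
    "systolic_bp": "mmHg",
    "urine_output_rate": "mL/(kg.h)",
    "drug_level_theophylline": "mg/L",
    "drug_level_digoxin": "ng/mL",
    "drug_level_vancomycin": "mg/L",
    "drug_level_gentamicin": "mg/L",
    "drug_level_carbamazepine": "mg/L",
}

EVENT_CODES = frozenset({
    "rash", "oversedation_fall", "delirium", "epilepsy", "cognitive_disorder",
    "edema", "hemorrhage", "dry_cough", "nausea_vomiting", "diarrhea",
    "myalgia", "ecg_abnormal", "dizziness", "headache", "sweating",
    "palpitation", "general_malaise", "vision_abnormal",
})

EVENT_CONTEXT_FLAGS = frozenset({"pre_existing_cough", "history_peptic_ulcer"})

COMORBIDITY_FLAGS = frozenset({
    "diabetes", "thyroid_dysfunction", "gout_or_hyperuricemia_history",
    "dementia_or_parkinson", "chronic_renal_failure",
    "hepatobiliary_pancreatic_disease", "primary_muscle_disease",
    "peptic_ulcer_history",
})

EXCLUDED_FLAGS = frozenset({
    "malignant_tumor", "organ_transplant", "palliative", "icu_transfer",
})

COHORT_FILES = ("admissions", "medications", "labs", "events", "context")

_COLUMNS = {
    "admissions": ["admission_id", "age", "sex", "admit_ts", "discharge_ts",
                   "length_of_stay", "n_diagnoses", "allergy_history",
                   "allergy_list", "excluded_flags"],
    "medications": ["admission_id", "drug_name", "drug_class", "start_ts",
                    "stop_ts", "abrupt_stop", "dose_reduced"],
    "labs": ["admission_id", "analyte", "value", "unit", "ts"],
    "events": ["admission_id", "code", "ts", "context_flags"],
    "context": ["admission_id", "comorbidity_flags", "on_parenteral_nutrition"],
}


class IOConfig(BaseModel):
    """Reader options.

    lookback_hours
        Pre-admission window accepted for baseline observations (a creatinine
        drawn shortly before admission still counts as the admission value).
    """

    lookback_hours: float = Field(default=48.0, ge=0)
    strict_event_codes: bool = True


def parse_set(cell) -> frozenset:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return frozenset()
    return frozenset(p for p in str(cell).split(";") if p)


def join_set(values: Iterable[str]) -> str:
    return ";".join(sorted(values))


# ---------------------------------------------------------------------------
# Container
# ---------------------------------------------------------------------------

@dataclass
class AdmissionView:
    """One admission plus all of its child rows, as the trigger engine sees it."""

    admission: pd.Series
    labs: pd.DataFrame
    meds: pd.DataFrame
    events: pd.DataFrame
    comorbidities: frozenset
    on_parenteral_nutrition: bool

    @property
    def admission_id(self) -> str:
        return str(self.admission["admission_id"])


@dataclass
class Cohort:
    """Validated cohort: five aligned tables keyed by ``admission_id``."""

    admissions: pd.DataFrame
    medications: pd.DataFrame
    labs: pd.DataFrame
    events: pd.DataFrame
    context: pd.DataFrame
    rejects: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["table", "row", "reason"]))

    @property
    def admission_ids(self) -> list:
        return list(self.admissions["admission_id"])

    @property
    def n_admissions(self) -> int:
        return len(self.admissions)

    def view(self, admission_id: str) -> AdmissionView:
        adm = self.admissions.loc[self.admissions["admission_id"] == admission_id]
        if adm.empty:
            raise KeyError(admission_id)
        ctx = self.context.loc[self.context["admission_id"] == admission_id]
        if ctx.empty:
            flags, pn = frozenset(), False
        else:
            flags = parse_set(ctx.iloc[0]["comorbidity_flags"])
            pn = bool(ctx.iloc[0]["on_parenteral_nutrition"])
        return AdmissionView(
            admission=adm.iloc[0],
            labs=self.labs.loc[self.labs["admission_id"] == admission_id]
                .sort_values("ts", kind="stable").reset_index(drop=True),
            meds=self.medications.loc[self.medications["admission_id"] == admission_id]
                .sort_values("start_ts", kind="stable").reset_index(drop=True),
            events=self.events.loc[self.events["admission_id"] == admission_id]
                .sort_values("ts", kind="stable").reset_index(drop=True),
            comorbidities=flags,
            on_parenteral_nutrition=pn,
        )

    def views(self):
        for aid in self.admission_ids:
            yield self.view(aid)


# ---------------------------------------------------------------------------
# Loading and validation
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, table: str) -> None:
    missing = [c for c in _COLUMNS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s) {missing}")


def _to_ts(value):
    if value is None or value == "" or (isinstance(value, float) and np.isnan(value)):
        return pd.NaT
    return pd.Timestamp(value)


def _to_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in {"true", "1", "yes"}


def _validate_admissions(df: pd.DataFrame):
    rows, rejects = [], []
    for i, r in df.iterrows():
        admit, disch = _to_ts(r["admit_ts"]), _to_ts(r["discharge_ts"])
        los = int(r["length_of_stay"])
        reason = None
        if str(r["sex"]) not in SEXES:
            reason = f"sex not in {sorted(SEXES)}"
        elif pd.isna(admit) or pd.isna(disch):
            reason = "unparseable timestamp"
        elif disch < admit:
            reason = "discharge_ts before admit_ts"
        elif los < 1:
            reason = "ineligible: length_of_stay below 1 day"
        if reason is not None:
            rejects.append(("admissions", i, reason))
            continue
        flags = parse_set(r["excluded_flags"])
        bad = flags - EXCLUDED_FLAGS
        if bad:
            rejects.append(("admissions", i, f"unknown excluded_flags {sorted(bad)}"))
            continue
        rows.append({
            "admission_id": str(r["admission_id"]), "age": int(r["age"]),
            "sex": str(r["sex"]), "admit_ts": admit, "discharge_ts": disch,
            "length_of_stay": los, "n_diagnoses": int(r["n_diagnoses"]),
            "allergy_history": _to_bool(r["allergy_history"]),
            "allergy_list": join_set(parse_set(r.get("allergy_list", ""))),
            "excluded_flags": join_set(flags),
        })
    return pd.DataFrame(rows, columns=_COLUMNS["admissions"]), rejects


def _window_ok(ts, admit, disch, lookback_h) -> bool:
    return (admit - pd.Timedelta(hours=lookback_h)) <= ts <= disch


def _validate_children(df, table, windows, config: IOConfig, rejected_ids=()):
    rows, rejects, orphans = [], [], []
    for i, r in df.iterrows():
        aid = str(r["admission_id"])
        if aid not in windows:
            if aid in rejected_ids:
                rejects.append((table, i, "parent admission row was rejected"))
            else:
                orphans.append((table, i, aid))
            continue
        admit, disch = windows[aid]
        if table == "medications":
            start, stop = _to_ts(r["start_ts"]), _to_ts(r["stop_ts"])
            if pd.isna(start):
                rejects.append((table, i, "missing start_ts")); continue
            if not pd.isna(stop) and stop < start:
                rejects.append((table, i, "stop_ts before start_ts")); continue
            if r["drug_class"] not in DRUG_CLASSES:
                rejects.append((table, i, f"unknown drug_class {r['drug_class']!r}")); continue
            if not _window_ok(start, admit, disch, config.lookback_hours):
                rejects.append((table, i, "start_ts outside admission window")); continue
            rows.append({"admission_id": aid, "drug_name": str(r["drug_name"]),
                         "drug_class": r["drug_class"], "start_ts": start,
                         "stop_ts": stop, "abrupt_stop": _to_bool(r["abrupt_stop"]),
                         "dose_reduced": _to_bool(r["dose_reduced"])})
        elif table == "labs":
            ts = _to_ts(r["ts"])
            analyte = str(r["analyte"])
            value = float(r["value"])
            if analyte not in ANALYTE_UNITS:
                rejects.append((table, i, f"unknown analyte {analyte!r}")); continue
            if str(r["unit"]) != ANALYTE_UNITS[analyte]:
                rejects.append((table, i,
                                f"unit {r['unit']!r} != {ANALYTE_UNITS[analyte]!r} for {analyte}")); continue
            if not np.isfinite(value):
                rejects.append((table, i, "non-finite value")); continue
            if pd.isna(ts) or not _window_ok(ts, admit, disch, config.lookback_hours):
                rejects.append((table, i, "ts outside admission window")); continue
            rows.append({"admission_id": aid, "analyte": analyte, "value": value,
                         "unit": str(r["unit"]), "ts": ts})
        elif table == "events":
            ts = _to_ts(r["ts"])
            code = str(r["code"])
            if config.strict_event_codes and code not in EVENT_CODES:
                rejects.append((table, i, f"unknown event code {code!r}")); continue
            flags = parse_set(r.get("context_flags", ""))
            if flags - EVENT_CONTEXT_FLAGS:
                rejects.append((table, i, "unknown context_flags")); continue
            if pd.isna(ts) or not _window_ok(ts, admit, disch, config.lookback_hours):
                rejects.append((table, i, "ts outside admission window")); continue
            rows.append({"admission_id": aid, "code": code, "ts": ts,
                         "context_flags": join_set(flags)})
        elif table == "context":
            flags = parse_set(r["comorbidity_flags"])
            if flags - COMORBIDITY_FLAGS:
                rejects.append((table, i, "unknown comorbidity_flags")); continue
            rows.append({"admission_id": aid, "comorbidity_flags": join_set(flags),
                         "on_parenteral_nutrition": _to_bool(r["on_parenteral_nutrition"])})
    return pd.DataFrame(rows, columns=_COLUMNS[table]), rejects, orphans


def load_cohort(paths, config: IOConfig | None = None) -> Cohort:
    """Read and validate the five cohort CSV files.

    ``paths`` is either a directory containing ``admissions.csv`` ... or a
    mapping from table name to file path. Rows that fail validation are
    collected into ``Cohort.rejects`` (never silently dropped); rows that
    reference a nonexistent admission raise :class:`ReferentialError`.
    """
    config = config or IOConfig()
    if isinstance(paths, (str, Path)):
        base = Path(paths)
        paths = {t: base / f"{t}.csv" for t in COHORT_FILES}
    frames = {}
    for table in COHORT_FILES:
        p = Path(paths[table])
        if not p.exists():
            raise SchemaError(f"missing input file for table {table!r}: {p}")
        df = pd.read_csv(p, dtype=str, keep_default_na=False)
        _require_columns(df, table)
        frames[table] = df
    return validate_cohort(frames, config)


def validate_cohort(frames: Mapping[str, pd.DataFrame], config: IOConfig | None = None) -> Cohort:
    """Validate in-memory raw frames into a :class:`Cohort` (same rules as load)."""
    config = config or IOConfig()
    for table in COHORT_FILES:
        _require_columns(frames[table], table)
    admissions, rejects = _validate_admissions(frames["admissions"])
    windows = {r["admission_id"]: (r["admit_ts"], r["discharge_ts"])
               for _, r in admissions.iterrows()}
    rejected_ids = {str(frames["admissions"].iloc[i]["admission_id"])
                    for t, i, _ in rejects if t == "admissions"}
    out, orphans_all = {}, []
    for table in ("medications", "labs", "events", "context"):
        out[table], rej, orphans = _validate_children(
            frames[table], table, windows, config, rejected_ids)
        rejects.extend(rej)
        orphans_all.extend(orphans)
    if orphans_all:
        listing = ", ".join(f"{t}[{i}]->{aid}" for t, i, aid in orphans_all[:20])
        raise ReferentialError(
            f"{len(orphans_all)} row(s) reference unknown admission_id: {listing}",
            rows=orphans_all)
    rej_df = pd.DataFrame(rejects, columns=["table", "row", "reason"])
    return Cohort(admissions=admissions, medications=out["medications"],
                  labs=out["labs"], events=out["events"], context=out["context"],
                  rejects=rej_df)


def write_cohort(cohort: Cohort, directory) -> dict:
    """Write the five cohort CSVs; round-trips ``load_cohort`` output field-for-field."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for table in COHORT_FILES:
        df = getattr(cohort, table if table != "context" else "context").copy()
        for col in df.columns:
            if df[col].dtype == "datetime64[ns]" or col.endswith("_ts"):
                df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%dT%H:%M")
                df[col] = df[col].fillna("")
        paths[table] = directory / f"{table}.csv"
        df.to_csv(paths[table], index=False)
    return paths


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

ELIGIBILITY_MIN_AGE = 65


def apply_eligibility(cohort: Cohort):
    """Retain admissions aged >= 65 with stay longer than one day and none of
    the exclusion conditions (malignant tumor, organ transplant, palliative
    care, ICU transfer). Returns ``(filtered_cohort, report)`` where ``report``
    counts admissions per exclusion reason; an admission with several reasons
    is counted under each. Idempotent.
    """
    report = {"age_below_65": 0, "length_of_stay_not_exceeding_1_day": 0,
              "malignant_tumor": 0, "organ_transplant": 0, "palliative": 0,
              "icu_transfer": 0, "n_excluded": 0, "n_retained": 0}
    keep = []
    for _, r in cohort.admissions.iterrows():
        reasons = []
        if int(r["age"]) < ELIGIBILITY_MIN_AGE:
            reasons.append("age_below_65")
        if int(r["length_of_stay"]) <= 1:
            reasons.append("length_of_stay_not_exceeding_1_day")
        reasons.extend(sorted(parse_set(r["excluded_flags"])))
        if reasons:
            report["n_excluded"] += 1
            for reason in reasons:
                report[reason] += 1
        else:
            keep.append(r["admission_id"])
    keep_set = set(keep)
    report["n_retained"] = len(keep)

    def _filter(df):
        return df.loc[df["admission_id"].isin(keep_set)].reset_index(drop=True)

    filtered = Cohort(
        admissions=_filter(cohort.admissions),
        medications=_filter(cohort.medications),
        labs=_filter(cohort.labs),
        events=_filter(cohort.events),
        context=_filter(cohort.context),
        rejects=cohort.rejects.copy(),
    )
    return filtered, report
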