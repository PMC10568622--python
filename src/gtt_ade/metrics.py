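"""Quantitative outputs: per-trigger and overall positive predictive value,
the three cohort surveillance rates, distribution tables, the monthly rate
series, and the proportion sample-size formula.

All quantities are computed in full precision; rounding to two decimals
happens only at rendering, using banker's (half-even) rounding.

The module works from either patient-level objects (hit table + adjudicated
ADEs) or from a summary-level :class:`StudyCounts` object — a counts-only
input that lets every headline rate be recomputed without patient rows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_EVEN

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .adjudication import ONSET_BINS, ORGAN_SYSTEMS
from .errors import ComputationError
from .triggers import TRIGGER_IDS


def round2(x: float) -> float:
    """Round to 2 decimals, ties to even (reproduces the reported rates)."""
    if x is None or (isinstance(x, float) and not np.isfinite(x)):
        return x
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_EVEN))


# ---------------------------------------------------------------------------
# PPV
# ---------------------------------------------------------------------------

def detection_counts_table(hits: pd.DataFrame, ades) -> pd.DataFrame:
    """Per-trigger positive firings and ADE detection pairs from data.

    A detection pair is one (ADE, linked trigger) association; an ADE linked
    to several triggers is counted once under each.
    """
    positives = hits.groupby("trigger_id").size() if len(hits) else pd.Series(dtype=int)
    detections: dict[str, int] = {}
    for ade in ades:
        for tid in ade.linked_hits:
            detections[tid] = detections.get(tid, 0) + 1
    return pd.DataFrame({
        "trigger_id": list(TRIGGER_IDS),
        "positive_count": [int(positives.get(t, 0)) for t in TRIGGER_IDS],
        "ade_detection_count": [int(detections.get(t, 0)) for t in TRIGGER_IDS],
    })


def ppv_table(counts: pd.DataFrame) -> pd.DataFrame:
    """PPV percent per trigger plus the overall (Total) row.

    PPV = 100 x detections / positives; undefined (NaN, rendered em-dash)
    for triggers that never fired.
    """
    df = counts.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        ppv = np.where(df["positive_count"] > 0,
                       100.0 * df["ade_detection_count"] / df["positive_count"],
                       np.nan)
    df["ppv_percent"] = ppv
    total_pos = int(df["positive_count"].sum())
    total_det = int(df["ade_detection_count"].sum())
    overall = np.nan if total_pos == 0 else 100.0 * total_det / total_pos
    total = pd.DataFrame([{"trigger_id": "Total", "positive_count": total_pos,
                           "ade_detection_count": total_det,
                           "ppv_percent": overall}])
    out = pd.concat([df, total], ignore_index=True)
    out["ppv_display"] = [
        "—" if not np.isfinite(v) else f"{round2(v):.2f}"
        for v in out["ppv_percent"]
    ]
    return out


def overall_ppv(counts: pd.DataFrame) -> float:
    table = ppv_table(counts)
    return float(table.loc[table["trigger_id"] == "Total", "ppv_percent"].iloc[0])


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

@dataclass
class RatePanel:
    n_admissions: int
    n_patients_with_ade: int
    n_ades: int
    total_patient_days: float
    incidence_percent: float = field(init=False)
    ades_per_100_admissions: float = field(init=False)
    ades_per_1000_patient_days: float = field(init=False)

    def __post_init__(self):
        if self.n_admissions <= 0:
            raise ComputationError("rate panel needs at least one admission")
        if self.total_patient_days <= 0:
            raise ComputationError("rate panel needs positive patient-days")
        self.incidence_percent = 100.0 * self.n_patients_with_ade / self.n_admissions
        self.ades_per_100_admissions = 100.0 * self.n_ades / self.n_admissions
        self.ades_per_1000_patient_days = 1000.0 * self.n_ades / self.total_patient_days

    def rounded(self) -> dict:
        d = asdict(self)
        for k in ("incidence_percent", "ades_per_100_admissions",
                  "ades_per_1000_patient_days"):
            d[k] = round2(d[k])
        return d


def rate_panel(adjudicated) -> RatePanel:
    """Rates from patient-level data; patient-days = sum of lengths of stay."""
    adm = adjudicated.cohort.admissions
    return RatePanel(
        n_admissions=len(adm),
        n_patients_with_ade=len({a.admission_id for a in adjudicated.ades}),
        n_ades=len(adjudicated.ades),
        total_patient_days=float(adm["length_of_stay"].sum()),
    )


def monthly_rate_series(adjudicated) -> pd.DataFrame:
    """Per-calendar-month ADEs/1,000 patient-days and ADEs/100 admissions.

    Admissions (and their patient-days and ADEs) are attributed to the month
    of admission; calendar months with zero admissions appear with missing
    rates.
    """
    adm = adjudicated.cohort.admissions
    if adm.empty:
        return pd.DataFrame(columns=["month", "n_admissions", "patient_days",
                                     "n_ades", "ades_per_100_admissions",
                                     "ades_per_1000_patient_days"])
    months = pd.period_range(adm["admit_ts"].min().to_period("M"),
                             adm["admit_ts"].max().to_period("M"), freq="M")
    adm = adm.assign(month=pd.to_datetime(adm["admit_ts"]).dt.to_period("M"))
    ade_month = {}
    month_of = dict(zip(adm["admission_id"], adm["month"]))
    for ade in adjudicated.ades:
        m = month_of[ade.admission_id]
        ade_month[m] = ade_month.get(m, 0) + 1
    rows = []
    for m in months:
        sub = adm.loc[adm["month"] == m]
        n, pdays = len(sub), float(sub["length_of_stay"].sum())
        n_ades = ade_month.get(m, 0)
        rows.append({
            "month": str(m), "n_admissions": n, "patient_days": pdays,
            "n_ades": n_ades,
            "ades_per_100_admissions": 100.0 * n_ades / n if n else np.nan,
            "ades_per_1000_patient_days": 1000.0 * n_ades / pdays if pdays else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Distribution tables
# ---------------------------------------------------------------------------

def _pct_table(counts: dict, order, total: int) -> pd.DataFrame:
    rows = [{"category": k, "count": int(counts.get(k, 0)),
             "percent": 100.0 * counts.get(k, 0) / total if total else np.nan}
            for k in order]
    return pd.DataFrame(rows)


def distribution_tables(ades, n_admissions: int | None = None) -> dict:
    """Onset-time, organ-system (symptom-entry level), severity and
    ADE-multiplicity tables with counts and percentages."""
    onset: dict[str, int] = {}
    organ: dict[str, int] = {}
    severity: dict[int, int] = {}
    per_patient: dict[str, int] = {}
    for ade in ades:
        onset[ade.onset_category] = onset.get(ade.onset_category, 0) + 1
        for o, _ in ade.organ_entries:
            organ[o] = organ.get(o, 0) + 1
        severity[ade.ctcae_grade] = severity.get(ade.ctcae_grade, 0) + 1
        per_patient[ade.admission_id] = per_patient.get(ade.admission_id, 0) + 1
    n_ades = len(ades)
    n_entries = sum(organ.values())
    multiplicity = {}
    for k in per_patient.values():
        multiplicity[k] = multiplicity.get(k, 0) + 1
    tables = {
        "onset": _pct_table(onset, ONSET_BINS, n_ades),
        "organ_system": _pct_table(organ, ORGAN_SYSTEMS, n_entries),
        "severity": _pct_table(severity, [1, 2, 3, 4, 5], n_ades),
    }
    denom = n_admissions if n_admissions else sum(multiplicity.values())
    tables["multiplicity"] = _pct_table(
        multiplicity, sorted(multiplicity) or [1], denom)
    return tables


# ---------------------------------------------------------------------------
# Sample size
# ---------------------------------------------------------------------------

class SampleSizeSpec(BaseModel):
    """N = Z^2 * P * (1 - P) / delta^2, rounded to the nearest integer."""

    P: float = Field(gt=0, lt=1)
    Z: float = Field(default=1.96, gt=0)
    delta: float = Field(gt=0)


def sample_size(spec: SampleSizeSpec) -> int:
    if spec.delta < 1e-6:
        raise ComputationError("sampling error delta too small (< 1e-6)")
    n = spec.Z ** 2 * spec.P * (1.0 - spec.P) / spec.delta ** 2
    return int(Decimal(repr(n)).quantize(Decimal("1"), rounding="ROUND_HALF_UP"))


# ---------------------------------------------------------------------------
# Summary-level study counts
# ---------------------------------------------------------------------------

class StudyCounts(BaseModel):
    """Counts-only description of a screened cohort; feeds every metric
    without patient rows. ``trigger_counts`` maps trigger id to
    (positive firings, ADE detection pairs)."""

    n_admissions: int
    mean_length_of_stay: float
    trigger_counts: dict[str, tuple[int, int]]
    patients_with_trigger: int
    n_ades: int
    n_patients_with_ade: int
    undetected_ades: int
    multiplicity: dict[int, int]
    severity: dict[int, int]
    during_stay: int
    onset_bins: dict[str, int]
    organ_entries: dict[str, int]

    @property
    def total_patient_days(self) -> float:
        return self.n_admissions * self.mean_length_of_stay

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trigger_id": list(TRIGGER_IDS),
            "positive_count": [self.trigger_counts.get(t, (0, 0))[0]
                               for t in TRIGGER_IDS],
            "ade_detection_count": [self.trigger_counts.get(t, (0, 0))[1]
                                    for t in TRIGGER_IDS],
        })

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.model_dump(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StudyCounts":
        with open(path) as fh:
            return cls(**json.load(fh))


def summary_from_counts(sc: StudyCounts) -> dict:
    """Every headline quantity recomputed from a counts-only fixture,
    rendered at two decimals."""
    counts = sc.counts_frame()
    table = ppv_table(counts)
    panel = RatePanel(sc.n_admissions, sc.n_patients_with_ade, sc.n_ades,
                      sc.total_patient_days)
    n_triggers = len(TRIGGER_IDS)
    n_fired = int((counts["positive_count"] > 0).sum())
    onset_total = sum(sc.onset_bins.values())
    organ_total = sum(sc.organ_entries.values())
    sev_total = sum(sc.severity.values())
    within_1d = sum(sc.onset_bins.get(b, 0) for b in ("<=5h", "5h-1d"))
    within_2d = within_1d + sc.onset_bins.get("1-2d", 0)
    per_trigger_ppv = {
        r["trigger_id"]: (round2(r["ppv_percent"])
                          if np.isfinite(r["ppv_percent"]) else None)
        for _, r in table.iterrows()}
    return {
        "overall_ppv_percent": round2(overall_ppv(counts)),
        "total_positive_triggers": int(counts["positive_count"].sum()),
        "total_detection_pairs": int(counts["ade_detection_count"].sum()),
        "incidence_percent": round2(panel.incidence_percent),
        "ades_per_100_admissions": round2(panel.ades_per_100_admissions),
        "ades_per_1000_patient_days": round2(panel.ades_per_1000_patient_days),
        "triggers_fired": n_fired,
        "triggers_fired_percent": round2(100.0 * n_fired / n_triggers),
        "patients_with_trigger_percent": round2(
            100.0 * sc.patients_with_trigger / sc.n_admissions),
        "grade1_percent": round2(100.0 * sc.severity.get(1, 0) / sev_total),
        "grade2_percent": round2(100.0 * sc.severity.get(2, 0) / sev_total),
        "grade3_percent": round2(100.0 * sc.severity.get(3, 0) / sev_total),
        "during_stay_percent": round2(100.0 * sc.during_stay / sc.n_ades),
        "onset_within_1d_percent": round2(100.0 * within_1d / onset_total),
        "onset_within_2d_percent": round2(100.0 * within_2d / onset_total),
        "gastro_intestinal_percent": round2(
            100.0 * sc.organ_entries.get("gastro_intestinal", 0) / organ_total),
        "per_trigger_ppv_percent": per_trigger_ppv,
    }
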