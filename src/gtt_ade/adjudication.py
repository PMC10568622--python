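"""Adjudication as data: Naranjo causality scoring, CTCAE severity grading,
onset-time binning, and linkage of adjudicated ADEs to trigger hits.

The human two-tier chart review is represented by an input file
(``adjudications.csv``): one row per candidate adverse drug event carrying the
ten Naranjo answers, a severity descriptor, onset/administration timestamps,
the involved organ system(s) and the trigger ids the reviewers linked. The
pipeline scores and validates those decisions; it never infers causality
itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from .errors import ReferentialError, ValidationError
from .records import Cohort, join_set, parse_set

ANSWERS = ("yes", "no", "unknown")
CATEGORIES = ("definite", "probable", "possible", "doubtful")
INCLUDED_CATEGORIES = frozenset({"definite", "probable"})

#: CTCAE v5 severity descriptors, in grade order 1..5.
CTCAE_DESCRIPTORS = (
    "mild_no_intervention",          # grade 1
    "minimal_local_noninvasive",     # grade 2
    "severe_or_hospitalization",     # grade 3
    "life_threatening",              # grade 4
    "death",                         # grade 5
)

ORGAN_SYSTEMS = (
    "gastro_intestinal", "metabolic_nutritional", "skin_appendages",
    "cardiovascular_general", "hepatobiliary", "cns_pns",
    "heart_rate_rhythm", "platelet_bleeding_clotting", "autonomic",
    "respiratory", "body_general", "vision",
)

ONSET_BINS = ("<=5h", "5h-1d", "1-2d", "2-4d", "4-8d", ">8d",
              "prior_to_admission")


def _load_instrument():
    path = Path(str(resources.files("gtt_ade").joinpath("data/naranjo.yaml")))
    raw = yaml.safe_load(path.read_text())
    weights = [{a: int(item[a]) for a in ANSWERS} for item in raw["items"]]
    return weights, raw["categories"]


_NARANJO_WEIGHTS, _NARANJO_CUTOFFS = _load_instrument()


class NaranjoAssessment(BaseModel):
    answers: tuple[str, ...]
    score: int
    category: str

    @field_validator("category")
    @classmethod
    def _known(cls, v):
        if v not in CATEGORIES:
            raise ValueError(v)
        return v


def naranjo_score(answers) -> NaranjoAssessment:
    """Score ten yes/no/unknown answers with the published item weights and
    classify: >= 9 definite, 5-8 probable, 1-4 possible, <= 0 doubtful."""
    answers = tuple(str(a).strip().lower() for a in answers)
    if len(answers) != 10:
        raise ValidationError(f"expected 10 Naranjo answers, got {len(answers)}")
    bad = [a for a in answers if a not in ANSWERS]
    if bad:
        raise ValidationError(f"invalid Naranjo answers {bad!r}")
    score = sum(w[a] for w, a in zip(_NARANJO_WEIGHTS, answers))
    return NaranjoAssessment(answers=answers, score=score,
                             category=naranjo_category(score))


def naranjo_category(score: int) -> str:
    if score >= _NARANJO_CUTOFFS["definite"]:
        return "definite"
    if score >= _NARANJO_CUTOFFS["probable"]:
        return "probable"
    if score >= _NARANJO_CUTOFFS["possible"]:
        return "possible"
    return "doubtful"


def ctcae_grade_from_descriptor(descriptor: str) -> int:
    """Map a severity descriptor to its CTCAE grade (1-5); bijective."""
    try:
        return CTCAE_DESCRIPTORS.index(descriptor) + 1
    except ValueError:
        raise ValidationError(
            f"unknown severity descriptor {descriptor!r}; "
            f"expected one of {CTCAE_DESCRIPTORS}") from None


def onset_bin(onset_ts, admin_ts, admit_ts) -> str:
    """Bin the administration-to-onset delay.

    An onset before admission is its own category (the event walked in the
    door with the patient). Otherwise bins are half-open (lower, upper] on
    ``onset_ts - admin_ts`` with the first bin closed at 5 hours.
    """
    onset_ts, admin_ts, admit_ts = (pd.Timestamp(onset_ts), pd.Timestamp(admin_ts),
                                    pd.Timestamp(admit_ts))
    if onset_ts < admit_ts:
        return "prior_to_admission"
    if onset_ts < admin_ts:
        raise ValidationError(
            "onset precedes drug administration but follows admission")
    hours = (onset_ts - admin_ts).total_seconds() / 3600.0
    if hours <= 5:
        return "<=5h"
    if hours <= 24:
        return "5h-1d"
    if hours <= 48:
        return "1-2d"
    if hours <= 96:
        return "2-4d"
    if hours <= 192:
        return "4-8d"
    return ">8d"


class ADERecord(BaseModel):
    """One adjudicated adverse drug event.

    ``organ_entries`` holds one or more (organ system, clinical symptom)
    pairs — an event such as drug-induced GI bleeding with rash involves
    several body systems, so symptom-level tabulations can total more entries
    than there are ADEs.
    """

    ade_id: str
    admission_id: str
    suspect_drugs: tuple[str, ...] = ()
    onset_ts: object
    admin_ts: object
    admit_ts: object
    organ_entries: tuple[tuple[str, str], ...]
    ctcae_grade: int = Field(ge=1, le=5)
    naranjo: NaranjoAssessment
    linked_hits: tuple[str, ...] = ()
    occurred_during_stay: bool = True
    medication_error: bool = False

    @field_validator("organ_entries")
    @classmethod
    def _known_organs(cls, v):
        for organ, _ in v:
            if organ not in ORGAN_SYSTEMS:
                raise ValueError(f"unknown organ system {organ!r}")
        return v

    @property
    def organ_system(self) -> str:
        return self.organ_entries[0][0]

    @property
    def onset_category(self) -> str:
        return onset_bin(self.onset_ts, self.admin_ts, self.admit_ts)

    @property
    def included(self) -> bool:
        return self.naranjo.category in INCLUDED_CATEGORIES


def causality_filter(ades):
    """Retain definite and probable events only; returns (included, counts)."""
    counts = {c: 0 for c in CATEGORIES}
    included = []
    for ade in ades:
        counts[ade.naranjo.category] += 1
        if ade.included:
            included.append(ade)
    return included, counts


@dataclass
class DetectionCounts:
    n_ades: int
    detected: int
    undetected: int
    pairs: int

    #: detection pairs per trigger id (an ADE linked to k triggers adds k pairs)
    def __post_init__(self):
        assert self.detected + self.undetected == self.n_ades


@dataclass
class AdjudicatedCohort:
    cohort: Cohort | None
    hits: pd.DataFrame
    ades: list


def link_ades_to_hits(ades, hits: pd.DataFrame, cohort: Cohort | None = None):
    """Partition ADEs into trigger-detected (>= 1 linked hit) vs undetected.

    A detection *pair* is one (ADE, trigger) link; an ADE found by several
    triggers contributes several pairs, so pairs >= detected. Every link must
    reference an existing (admission, trigger) hit.
    """
    hit_keys = set(zip(hits["admission_id"], hits["trigger_id"])) if len(hits) else set()
    detected = pairs = 0
    per_trigger: dict[str, int] = {}
    for ade in ades:
        for tid in ade.linked_hits:
            if (ade.admission_id, tid) not in hit_keys:
                raise ReferentialError(
                    f"ADE {ade.ade_id} links trigger {tid} with no matching hit "
                    f"for admission {ade.admission_id}")
            per_trigger[tid] = per_trigger.get(tid, 0) + 1
            pairs += 1
        if ade.linked_hits:
            detected += 1
    counts = DetectionCounts(n_ades=len(ades), detected=detected,
                             undetected=len(ades) - detected, pairs=pairs)
    adjudicated = AdjudicatedCohort(cohort=cohort, hits=hits, ades=list(ades))
    return adjudicated, counts, per_trigger


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_ADJ_COLUMNS = (["ade_id", "admission_id", "suspect_drugs", "onset_ts", "admin_ts",
                 "admit_ts", "organ_system", "clinical_symptom",
                 "severity_descriptor"]
                + [f"q{i}" for i in range(1, 11)]
                + ["linked_triggers", "occurred_during_stay", "medication_error"])


def read_adjudications(path) -> list[ADERecord]:
    """Read reviewer adjudications; multi-entry organ/symptom columns are
    semicolon-separated and pair positionally."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _ADJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"adjudications file missing column(s) {missing}")
    ades = []
    for _, r in df.iterrows():
        organs = [o for o in str(r["organ_system"]).split(";") if o]
        symptoms = [s for s in str(r["clinical_symptom"]).split(";") if s]
        if len(symptoms) < len(organs):
            symptoms += [""] * (len(organs) - len(symptoms))
        ades.append(ADERecord(
            ade_id=str(r["ade_id"]), admission_id=str(r["admission_id"]),
            suspect_drugs=tuple(sorted(parse_set(r["suspect_drugs"]))),
            onset_ts=pd.Timestamp(r["onset_ts"]),
            admin_ts=pd.Timestamp(r["admin_ts"]),
            admit_ts=pd.Timestamp(r["admit_ts"]),
            organ_entries=tuple(zip(organs, symptoms)),
            ctcae_grade=ctcae_grade_from_descriptor(r["severity_descriptor"]),
            naranjo=naranjo_score([r[f"q{i}"] for i in range(1, 11)]),
            linked_hits=tuple(t for t in str(r["linked_triggers"]).split(";") if t),
            occurred_during_stay=str(r["occurred_during_stay"]).lower() in
                {"true", "1", "yes"},
            medication_error=str(r["medication_error"]).lower() in
                {"true", "1", "yes"},
        ))
    return ades


def write_adjudications(ades, path, answers_lookup=None) -> None:
    rows = []
    for ade in ades:
        grade_desc = CTCAE_DESCRIPTORS[ade.ctcae_grade - 1]
        rows.append({
            "ade_id": ade.ade_id, "admission_id": ade.admission_id,
            "suspect_drugs": join_set(ade.suspect_drugs),
            "onset_ts": pd.Timestamp(ade.onset_ts).strftime("%Y-%m-%dT%H:%M"),
            "admin_ts": pd.Timestamp(ade.admin_ts).strftime("%Y-%m-%dT%H:%M"),
            "admit_ts": pd.Timestamp(ade.admit_ts).strftime("%Y-%m-%dT%H:%M"),
            "organ_system": ";".join(o for o, _ in ade.organ_entries),
            "clinical_symptom": ";".join(s for _, s in ade.organ_entries),
            "severity_descriptor": grade_desc,
            **{f"q{i + 1}": a for i, a in enumerate(ade.naranjo.answers)},
            "linked_triggers": ";".join(ade.linked_hits),
            "occurred_during_stay": ade.occurred_during_stay,
            "medication_error": ade.medication_error,
        })
    pd.DataFrame(rows, columns=_ADJ_COLUMNS).to_csv(path, index=False)
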