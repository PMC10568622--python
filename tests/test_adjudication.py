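"""Naranjo scoring, CTCAE mapping, onset binning and ADE-hit linkage."""

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gtt_ade import (causality_filter, ctcae_grade_from_descriptor,
                     link_ades_to_hits, naranjo_score, onset_bin)
from gtt_ade.adjudication import (ADERecord, CTCAE_DESCRIPTORS,
                                  naranjo_category, read_adjudications,
                                  write_adjudications)
from gtt_ade.errors import ReferentialError, ValidationError

ADMIT = pd.Timestamp("2021-03-01T08:00")


def _ade(ade_id="E1", admission_id="A1", category="probable", links=(),
         onset_h=10.0, grade=2):
    patterns = {
        "definite": ("yes",) * 4 + ("no", "no") + ("yes",) * 4,
        "probable": ("yes", "yes", "yes", "unknown", "no", "unknown",
                     "unknown", "yes", "unknown", "yes"),
        "possible": ("unknown", "yes") + ("unknown",) * 8,
        "doubtful": ("unknown",) * 10,
    }
    admin = ADMIT + pd.Timedelta(hours=2)
    return ADERecord(
        ade_id=ade_id, admission_id=admission_id, suspect_drugs=("digoxin",),
        onset_ts=admin + pd.Timedelta(hours=onset_h), admin_ts=admin,
        admit_ts=ADMIT, organ_entries=(("gastro_intestinal", "nausea"),),
        ctcae_grade=grade, naranjo=naranjo_score(patterns[category]),
        linked_hits=tuple(links))


def test_all_unknown_scores_zero_doubtful():
    a = naranjo_score(("unknown",) * 10)
    assert a.score == 0 and a.category == "doubtful"


def test_published_weight_sum_example():
    # item weights +1,+2,+1,0,+2,0,0,+1,0,+1 sum to 8 -> probable
    a = naranjo_score(("yes", "yes", "yes", "unknown", "no", "unknown",
                       "unknown", "yes", "unknown", "yes"))
    assert a.score == 8 and a.category == "probable"


@pytest.mark.parametrize("score,category", [
    (13, "definite"), (9, "definite"), (8, "probable"), (5, "probable"),
    (4, "possible"), (1, "possible"), (0, "doubtful"), (-3, "doubtful")])
def test_category_cutoffs(score, category):
    assert naranjo_category(score) == category


def test_wrong_answer_count_rejected():
    with pytest.raises(ValidationError):
        naranjo_score(("yes",) * 9)
    with pytest.raises(ValidationError):
        naranjo_score(("maybe",) + ("unknown",) * 9)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.tuples(*[st.sampled_from(["yes", "no", "unknown"])] * 10))
def test_category_is_monotone_step_function_of_score(answers):
    a = naranjo_score(answers)
    order = {"doubtful": 0, "possible": 1, "probable": 2, "definite": 3}
    harsher = naranjo_category(a.score - 1)
    assert order[harsher] <= order[a.category]


def test_ctcae_descriptor_mapping_is_bijective():
    grades = [ctcae_grade_from_descriptor(d) for d in CTCAE_DESCRIPTORS]
    assert grades == [1, 2, 3, 4, 5]
    assert ctcae_grade_from_descriptor("minimal_local_noninvasive") == 2
    assert ctcae_grade_from_descriptor("death") == 5
    with pytest.raises(ValidationError):
        ctcae_grade_from_descriptor("catastrophic")


@pytest.mark.parametrize("onset_h,expected", [
    (4.0, "<=5h"), (5.0, "<=5h"), (5.5, "5h-1d"), (24.0, "5h-1d"),
    (24.5, "1-2d"), (48.0, "1-2d"), (72.0, "2-4d"), (120.0, "4-8d"),
    (200.0, ">8d")])
def test_onset_bins_half_open_upper_closed(onset_h, expected):
    admin = ADMIT + pd.Timedelta(hours=1)
    assert onset_bin(admin + pd.Timedelta(hours=onset_h), admin, ADMIT) == expected


def test_onset_before_admission_is_prior():
    admin = ADMIT - pd.Timedelta(days=5)
    onset = ADMIT - pd.Timedelta(days=3)
    assert onset_bin(onset, admin, ADMIT) == "prior_to_admission"


def test_onset_before_administration_in_stay_is_error():
    admin = ADMIT + pd.Timedelta(days=2)
    with pytest.raises(ValidationError):
        onset_bin(ADMIT + pd.Timedelta(days=1), admin, ADMIT)


def test_causality_filter_keeps_definite_and_probable_only():
    ades = [_ade("E1", category="definite"), _ade("E2", category="probable"),
            _ade("E3", category="possible"), _ade("E4", category="doubtful")]
    included, counts = causality_filter(ades)
    assert [a.ade_id for a in included] == ["E1", "E2"]
    assert counts == {"definite": 1, "probable": 1, "possible": 1, "doubtful": 1}
    again, _ = causality_filter(included)
    assert [a.ade_id for a in again] == ["E1", "E2"]
    assert causality_filter([]) == ([], {c: 0 for c in
                                         ("definite", "probable", "possible",
                                          "doubtful")})


def _hits(pairs):
    return pd.DataFrame([{"admission_id": a, "trigger_id": t,
                          "ts": ADMIT, "evidence": "[]"} for a, t in pairs],
                        columns=["admission_id", "trigger_id", "ts", "evidence"])


def test_linkage_counts_pairs_with_multiplicity():
    hits = _hits([("A1", "L15"), ("A1", "I1"), ("A2", "C1")])
    ades = [_ade("E1", "A1", links=("L15", "I1")),
            _ade("E2", "A2", links=("C1",)),
            _ade("E3", "A2", links=())]
    _, counts, per_trigger = link_ades_to_hits(ades, hits)
    assert counts.detected == 2 and counts.undetected == 1
    assert counts.pairs == 3
    assert per_trigger == {"L15": 1, "I1": 1, "C1": 1}
    assert counts.detected + counts.undetected == counts.n_ades


def test_link_to_missing_hit_is_referential_error():
    with pytest.raises(ReferentialError):
        link_ades_to_hits([_ade("E1", "A1", links=("L15",))], _hits([]))


def test_no_hits_means_all_undetected():
    ades = [_ade("E1"), _ade("E2")]
    _, counts, _ = link_ades_to_hits(ades, _hits([]))
    assert counts.undetected == 2 and counts.pairs == 0


def test_adjudication_csv_round_trip(tmp_path):
    ades = [_ade("E1", category="definite", links=()),
            _ade("E2", category="probable", grade=3)]
    path = tmp_path / "adjudications.csv"
    write_adjudications(ades, path)
    again = read_adjudications(path)
    assert [a.ade_id for a in again] == ["E1", "E2"]
    assert [a.naranjo.category for a in again] == ["definite", "probable"]
    assert again[1].ctcae_grade == 3
    assert again[0].organ_entries == (("gastro_intestinal", "nausea"),)
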