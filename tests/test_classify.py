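"""Clinical rule table, episode dedup, composite grouping and flow QC."""

import itertools

import numpy as np
import pandas as pd
import pytest

from neosep.classify import (
    ClassificationError,
    classify_sample,
    classify_samples,
    composite_groups,
    dedup_episodes,
    qc_filter,
)


def sample(**kw):
    base = {
        "draw_reason": "routine",
        "culture_result": "none",
        "organism": "",
        "organism_is_cons": False,
        "cons_supporting_evidence": False,
        "antibiotic_course_days": 0.0,
        "antibiotics_stopped_within_72h": False,
        "clinical_criteria_met": 0,
        "nec_stage": "none",
    }
    base.update(kw)
    return base


@pytest.mark.parametrize(
    "kw,expected",
    [
        # contemporaneous positive culture -> confirmed sepsis
        (
            dict(draw_reason="suspected_sepsis", culture_result="positive", organism="E. coli"),
            "MCS",
        ),
        # suspicion + negative cultures + >=3 criteria + >=5-day course
        (
            dict(
                draw_reason="suspected_sepsis",
                culture_result="negative",
                clinical_criteria_met=3,
                antibiotic_course_days=5.0,
            ),
            "ClinSep",
        ),
        # suspicion + negative cultures + antibiotics stopped at 48 h
        (
            dict(
                draw_reason="suspected_sepsis",
                culture_result="negative",
                antibiotic_course_days=2.0,
                antibiotics_stopped_within_72h=True,
            ),
            "NSC",
        ),
        # routine draw, nothing suspicious
        (dict(), "Stable"),
        # Bell stage II/III outranks everything, even a positive culture
        (
            dict(nec_stage="III", culture_result="positive", organism="E. coli"),
            "NEC",
        ),
        # unsupported CoNS is a contaminant: falls through to ClinSep here
        (
            dict(
                draw_reason="suspected_sepsis",
                culture_result="positive",
                organism="CoNS",
                organism_is_cons=True,
                cons_supporting_evidence=False,
                clinical_criteria_met=4,
                antibiotic_course_days=6.0,
            ),
            "ClinSep",
        ),
        # supported CoNS is valid confirmed sepsis
        (
            dict(
                draw_reason="suspected_sepsis",
                culture_result="positive",
                organism="CoNS",
                organism_is_cons=True,
                cons_supporting_evidence=True,
            ),
            "MCS",
        ),
    ],
)
def test_rule_table_examples(kw, expected):
    assert classify_sample(sample(**kw)).category == expected


def test_contradictory_metadata_raises():
    with pytest.raises(ClassificationError, match="organism"):
        classify_sample(sample(organism="E. coli", culture_result="none"))
    with pytest.raises(ClassificationError, match="without an organism"):
        classify_sample(sample(culture_result="positive"))


def test_uncovered_suspected_sample_raises():
    # suspected, 2 criteria, 4-day course, not stopped: no category fits
    with pytest.raises(ClassificationError, match="neither ClinSep"):
        classify_sample(
            sample(
                draw_reason="suspected_sepsis",
                culture_result="negative",
                clinical_criteria_met=2,
                antibiotic_course_days=4.0,
            )
        )


def _oracle(s):
    """Independent hand-written rule table (returns None where no rule fires)."""
    if s["nec_stage"] in ("II", "III"):
        return "NEC"
    pos = s["culture_result"] == "positive"
    valid_pos = pos and (not s["organism_is_cons"] or s["cons_supporting_evidence"])
    if valid_pos:
        return "MCS"
    if s["draw_reason"] == "suspected_sepsis":
        if s["clinical_criteria_met"] >= 3 and s["antibiotic_course_days"] >= 5:
            return "ClinSep"
        if s["antibiotics_stopped_within_72h"]:
            return "NSC"
        return None
    return "Stable"


def test_truth_table_equivalence():
    """Exhaustive enumeration of metadata combinations matches the oracle."""
    grid = itertools.product(
        ("none", "II"),  # nec_stage
        (False, True),  # positive culture
        (False, True),  # organism_is_cons
        (False, True),  # cons_supporting_evidence
        ("routine", "suspected_sepsis"),
        (0, 3),  # criteria
        (2.0, 6.0),  # course days
        (False, True),  # stopped within 72 h
    )
    n_checked = 0
    for nec, pos, cons, supp, reason, crit, course, stopped in grid:
        if cons and not pos:
            continue  # CoNS flag only meaningful with a positive culture
        s = sample(
            nec_stage=nec,
            culture_result="positive" if pos else "negative",
            organism=("CoNS" if cons else "E. coli") if pos else "",
            organism_is_cons=cons,
            cons_supporting_evidence=supp,
            draw_reason=reason,
            clinical_criteria_met=crit,
            antibiotic_course_days=course,
            antibiotics_stopped_within_72h=stopped,
        )
        expected = _oracle(s)
        if expected is None:
            with pytest.raises(ClassificationError):
                classify_sample(s)
        else:
            assert classify_sample(s).category == expected
        n_checked += 1
    assert n_checked > 150


def test_classification_total_on_generated_cohort(deduped):
    assert set(deduped["category"]) <= {"MCS", "ClinSep", "NSC", "Stable", "NEC"}
    assert deduped["category"].notna().all()


def _episode_df(days_by_episode):
    rows = []
    for ep, days in days_by_episode.items():
        for d in days:
            rows.append({"episode_id": ep, "postnatal_day": d})
    return pd.DataFrame(rows)


def test_dedup_keeps_earliest():
    df = _episode_df({"E1": [10, 12, 17]})
    out = dedup_episodes(df)
    assert out["postnatal_day"].tolist() == [10]


def test_dedup_identity_and_idempotence():
    df = _episode_df({"E1": [10], "E2": [20]})
    df.loc[len(df)] = {"episode_id": "", "postnatal_day": 5}
    out = dedup_episodes(df)
    pd.testing.assert_frame_equal(out, df)
    once = dedup_episodes(_episode_df({"E1": [10, 12], "E2": [20, 25]}))
    twice = dedup_episodes(once)
    pd.testing.assert_frame_equal(once, twice)


def test_dedup_47_to_32():
    # 32 episodes; 15 of them carry one later-in-episode repeat sample
    days = {f"E{i}": [10 + i] for i in range(32)}
    for i in range(15):
        days[f"E{i}"].append(13 + i)
    df = _episode_df(days)
    assert len(df) == 47
    assert len(dedup_episodes(df)) == 32


def test_dedup_same_day_warning():
    df = _episode_df({"E1": [10, 10]})
    with pytest.warns(UserWarning, match="day 10"):
        out = dedup_episodes(df)
    assert out.index.tolist() == [0]


def test_composite_counts_match_study_structure():
    counts = {"MCS": 26, "ClinSep": 21, "NSC": 22, "Stable": 82, "NEC": 6}
    df = pd.DataFrame({"category": sum(([k] * v for k, v in counts.items()), [])})
    groups = composite_groups(df)
    assert len(groups["NoSepsis"]) == 104
    assert len(groups["Sepsis"]) == 47
    assert len(groups["excluded"]) == 6
    assert sum(map(len, groups.values())) == len(df)


def test_composite_edge_cases():
    all_stable = pd.DataFrame({"category": ["Stable"] * 4})
    g = composite_groups(all_stable)
    assert len(g["Sepsis"]) == 0 and len(g["NoSepsis"]) == 4
    nec_only = pd.DataFrame({"category": ["NEC"] * 3})
    g = composite_groups(nec_only)
    assert len(g["Sepsis"]) == 0 and len(g["NoSepsis"]) == 0 and len(g["excluded"]) == 3
    with pytest.raises(ValueError):
        composite_groups(pd.DataFrame({"x": [1]}))


def test_qc_filter_boundary():
    df = pd.DataFrame(
        {
            "param.x": [1.0, 2.0, 3.0],
            "events.x": [29, 30, 500],
            "param.y": [5.0, 6.0, 7.0],
            "events.y": [100, 100, 100],
        }
    )
    out = qc_filter(df, min_events=30)
    assert np.isnan(out.loc[0, "param.x"])  # 29 events: blanked
    assert out.loc[1, "param.x"] == 2.0  # exactly 30: retained
    assert out["param.y"].notna().all()  # untouched column
    pd.testing.assert_frame_equal(qc_filter(out, min_events=30), out)  # identity when clean
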