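"""Outcome construction verified by hand bookkeeping on toy cohorts."""

import numpy as np
import pandas as pd
import pytest

from dietscore.outcomes import (
    DeathRecord,
    build_enduring_status,
    incident_outcome,
    mortality_outcome,
    multimorbidity_outcome,
    select_analysis_sample,
)
from dietscore.records import ValidationError

from conftest import toy_reports


def _all_responded(ids):
    return pd.DataFrame(True, index=pd.Index(ids, name="participant_id"), columns=range(1, 9))


def test_enduring_condition_is_retained():
    st = build_enduring_status(toy_reports([("a", 5, "HT")]), responded=_all_responded(["a"]))
    assert list(st.enduring["HT"].loc["a", [4, 5, 6, 7, 8]]) == [0, 1, 1, 1, 1]


def test_depression_anxiety_fluctuates():
    st = build_enduring_status(
        toy_reports([("a", 4, "depression")]), responded=_all_responded(["a"])
    )
    assert st.dep_anx.loc["a", 4] == 1
    assert st.dep_anx.loc["a", 5] == 0


def test_no_reports_all_zero():
    st = build_enduring_status(toy_reports([]), responded=_all_responded(["a"]))
    assert st.group_count(5).loc["a"] == 0


def test_conflicting_duplicates_rejected():
    reports = toy_reports([("a", 4, "DM")])
    reports = pd.concat(
        [reports, pd.DataFrame([{"participant_id": "a", "wave": 4, "condition": "DM", "reported": 0}])],
        ignore_index=True,
    )
    with pytest.raises(ValidationError, match="a"):
        build_enduring_status(reports, responded=_all_responded(["a"]))


def test_sample_selection_flow():
    """Hand-built five-person flow: one baseline HT exclusion, one
    pre-baseline depression kept, one incomplete FFQ, one S3 non-response,
    one never followed up."""
    ids = ["ht_s2", "dep_s2", "no_ffq", "no_s3", "no_follow"]
    responded = _all_responded(ids)
    responded.loc["no_s3", 3] = False
    responded.loc["no_follow", [4, 5, 6, 7, 8]] = False
    reports = toy_reports([("ht_s2", 2, "HT"), ("dep_s2", 2, "depression")])
    st = build_enduring_status(reports, responded=responded)
    ffq = pd.Series(True, index=ids)
    ffq.loc["no_ffq"] = False
    eligible, counts = select_analysis_sample(st, ffq)
    assert list(eligible) == ["dep_s2"]
    assert counts["excluded_ncd_at_or_before_s3"] == 1
    assert counts["excluded_ffq_incomplete"] == 1
    assert counts["excluded_not_responded_s3"] == 1
    assert counts["excluded_no_follow_up"] == 1
    assert counts["eligible"] == 1


def test_everyone_kept_when_nothing_excludes():
    ids = [f"p{i}" for i in range(10)]
    st = build_enduring_status(toy_reports([]), responded=_all_responded(ids))
    eligible, counts = select_analysis_sample(st, pd.Series(True, index=ids))
    assert len(eligible) == 10 and counts["eligible"] == 10


def test_incident_outcome_temporality():
    ids = ["a", "b"]
    st = build_enduring_status(
        toy_reports([("a", 6, "DM"), ("b", 5, "DM")]), responded=_all_responded(ids)
    )
    sample = pd.Index(ids)
    assert incident_outcome(st, 7, "DM", sample).loc["a"] == 1  # accumulates
    assert incident_outcome(st, 4, "DM", sample).loc["b"] == 0  # not yet reported
    assert incident_outcome(st, 8, "DM", sample).loc["b"] == 1
    with pytest.raises(ValidationError):
        incident_outcome(st, 3, "DM", sample)


def test_multimorbidity_group_counting():
    """Brute-force group counting: depression + anxiety form ONE group, so
    the pair alone is not multimorbidity; adding any enduring condition is."""
    ids = ["pair", "pair_plus_ht", "ht_only", "ht_dm"]
    rows = [
        ("pair", 5, "depression"), ("pair", 5, "anxiety"),
        ("pair_plus_ht", 5, "depression"), ("pair_plus_ht", 5, "anxiety"),
        ("pair_plus_ht", 4, "HT"),
        ("ht_only", 4, "HT"),
        ("ht_dm", 4, "HT"), ("ht_dm", 5, "DM"),
    ]
    st = build_enduring_status(toy_reports(rows), responded=_all_responded(ids))
    mm = multimorbidity_outcome(st, 5, pd.Index(ids))
    assert mm.loc["pair"] == 0
    assert mm.loc["pair_plus_ht"] == 1
    assert mm.loc["ht_only"] == 0
    assert mm.loc["ht_dm"] == 1


def test_mortality_bookkeeping_on_toy_cohort():
    """Ten women, deaths between S4-S5 and S5-S6: each death counts once,
    at the interval's closing wave, and leaves later denominators."""
    ids = [f"p{i}" for i in range(10)]
    deaths = [DeathRecord("p0", 5), DeathRecord("p1", 6)]
    sample = pd.Index(ids)
    y5 = mortality_outcome(deaths, 5, sample)
    assert y5.loc["p0"] == 1 and y5.sum() == 1 and len(y5) == 10
    y6 = mortality_outcome(deaths, 6, sample)
    assert "p0" not in y6.index and y6.loc["p1"] == 1 and len(y6) == 9
    y7 = mortality_outcome(deaths, 7, sample)
    assert len(y7) == 8 and y7.sum() == 0
    # per-wave incident deaths sum to total deaths in S3-S8 intervals
    total = sum(mortality_outcome(deaths, w, sample).sum() for w in range(4, 9))
    assert total == len(deaths)


def test_mortality_ncd_subset_scope():
    ids = ["with_ncd", "without_ncd"]
    st = build_enduring_status(toy_reports([("with_ncd", 4, "HT")]), responded=_all_responded(ids))
    deaths = [DeathRecord("with_ncd", 6)]
    y = mortality_outcome(deaths, 6, pd.Index(ids), scope="ncd_subset", status=st)
    assert list(y.index) == ["with_ncd"] and y.loc["with_ncd"] == 1


def test_death_interval_validated():
    with pytest.raises(ValidationError):
        DeathRecord("p", 3)
    with pytest.raises(ValidationError):
        DeathRecord("p", 9)


def test_dead_never_respond_later():
    responded = _all_responded(["a"])
    st = build_enduring_status(toy_reports([]), [DeathRecord("a", 6)], responded)
    assert st.responded.loc["a", 5]
    assert not st.responded.loc["a", 6] and not st.responded.loc["a", 8]


def test_enduring_monotone_on_generated_cohort(small_cohort):
    st = build_enduring_status(small_cohort.reports, small_cohort.deaths, small_cohort.responded)
    for cond, wide in st.enduring.items():
        assert (wide.diff(axis=1).fillna(0) >= 0).all().all(), cond
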