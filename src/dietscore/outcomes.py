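"""Cohort outcome construction: enduring NCD status, eligibility flow,
incident disease, multimorbidity, and all-cause mortality.

Surveys are integers 1..8 (three-yearly waves).  Five conditions - diabetes
(DM), coronary heart disease (CHD), hypertension (HT), asthma, and non-skin
cancer - are *enduring*: once reported at any wave, status stays 1 at every
later wave regardless of subsequent reports.  Depression and/or anxiety is a
single combined group whose status may fluctuate wave to wave.

The analysis sample mirrors a baseline-at-S3 design: respondents at S3 with
complete dietary data, at least one response over S4-S8, and none of the
five enduring conditions reported at or before S3 (a depression/anxiety
history does not exclude).  Outcomes at S4-S8 are then cumulative incident
status among that wave's respondents; deaths are assigned to the
between-survey interval in which they occurred, and each wave's mortality
denominator drops deaths from earlier intervals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .records import ValidationError

WAVES = tuple(range(1, 9))
OUTCOME_WAVES = tuple(range(4, 9))
BASELINE_WAVE = 3

ENDURING_CONDITIONS = ("DM", "CHD", "HT", "asthma", "cancer_nonskin")
EPISODIC_CONDITIONS = ("depression", "anxiety")
CONDITIONS = ENDURING_CONDITIONS + EPISODIC_CONDITIONS
#: the six outcome groups counted for multimorbidity
CONDITION_GROUPS = ENDURING_CONDITIONS + ("dep_anx",)


@dataclass(frozen=True)
class DeathRecord:
    """A death assigned to the survey interval ending at ``interval_end``
    (e.g. a death between S4 and S5 has interval_end 5)."""

    participant_id: str
    interval_end: int

    def __post_init__(self) -> None:
        if self.interval_end not in OUTCOME_WAVES:
            raise ValidationError(
                f"death interval for {self.participant_id!r} ends at wave "
                f"{self.interval_end}; must end in S4..S8"
            )


class StatusTable:
    """Participant x wave condition statuses plus vital/response flags.

    ``enduring`` maps each enduring condition to a participant x wave 0/1
    DataFrame (non-decreasing across waves); ``dep_anx`` is the per-wave
    current depression-and/or-anxiety status; ``alive`` and ``responded``
    are boolean participant x wave DataFrames.
    """

    def __init__(
        self,
        enduring: dict[str, pd.DataFrame],
        dep_anx: pd.DataFrame,
        alive: pd.DataFrame,
        responded: pd.DataFrame,
    ) -> None:
        self.enduring = enduring
        self.dep_anx = dep_anx
        self.alive = alive
        self.responded = responded

    @property
    def participants(self) -> pd.Index:
        return self.dep_anx.index

    def status_at(self, condition: str, wave: int) -> pd.Series:
        """0/1 status of one condition group at one wave."""
        if condition == "dep_anx":
            return self.dep_anx[wave]
        return self.enduring[condition][wave]

    def group_count(self, wave: int) -> pd.Series:
        """Number of the six condition groups present at a wave."""
        total = self.dep_anx[wave].copy()
        for cond in ENDURING_CONDITIONS:
            total = total + self.enduring[cond][wave]
        return total

    def dep_anx_history(self, wave: int) -> pd.Series:
        """1 if depression and/or anxiety was reported at any wave before
        ``wave`` (the history covariate for adjusted models)."""
        prior = [w for w in WAVES if w < wave]
        return (self.dep_anx[prior].sum(axis=1) > 0).astype(int)

    def ever_any_ncd(self, through_wave: int = 8) -> pd.Series:
        """1 if any of the six condition groups was present at any wave up
        to ``through_wave`` (the mortality-model NCD covariate / subset)."""
        waves = [w for w in WAVES if w <= through_wave]
        any_ncd = self.dep_anx[waves].sum(axis=1) > 0
        for cond in ENDURING_CONDITIONS:
            any_ncd |= self.enduring[cond][waves].sum(axis=1) > 0
        return any_ncd.astype(int)


def build_enduring_status(
    reports: pd.DataFrame,
    deaths: Iterable[DeathRecord] = (),
    responded: pd.DataFrame | None = None,
) -> StatusTable:
    """Roll per-survey condition reports into a StatusTable.

    ``reports`` has columns participant_id, wave, condition, reported
    (0/1).  Duplicate (participant, wave, condition) rows with conflicting
    values raise; consistent duplicates collapse.  ``responded`` is a
    boolean participant x wave DataFrame (defaults to all-responded for
    participants appearing in the reports).
    """
    reports = reports.copy()
    reports["participant_id"] = reports["participant_id"].astype(str)
    bad_cond = set(reports["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValidationError(f"unknown conditions in reports: {sorted(bad_cond)}")
    bad_wave = set(reports["wave"]) - set(WAVES)
    if bad_wave:
        raise ValidationError(f"report waves outside S1..S8: {sorted(bad_wave)}")

    key = ["participant_id", "wave", "condition"]
    conflict = reports.groupby(key)["reported"].nunique()
    if (conflict > 1).any():
        ids = sorted({i for i, _, _ in conflict[conflict > 1].index})
        raise ValidationError(f"conflicting duplicate condition reports for: {ids}")
    reports = reports.drop_duplicates(key)

    if responded is not None:
        participants = responded.index.astype(str)
    else:
        participants = pd.Index(sorted(reports["participant_id"].unique()))
    participants = pd.Index(participants, name="participant_id")

    def _pivot(sub: pd.DataFrame) -> pd.DataFrame:
        wide = sub.pivot_table(
            index="participant_id", columns="wave", values="reported", aggfunc="max"
        )
        return wide.reindex(index=participants, columns=list(WAVES)).fillna(0).astype(int)

    enduring = {}
    for cond in ENDURING_CONDITIONS:
        wide = _pivot(reports[reports["condition"] == cond])
        enduring[cond] = wide.cummax(axis=1)

    dep = _pivot(reports[reports["condition"] == "depression"])
    anx = _pivot(reports[reports["condition"] == "anxiety"])
    dep_anx = ((dep + anx) > 0).astype(int)

    alive = pd.DataFrame(True, index=participants, columns=list(WAVES))
    death_list = list(deaths)
    seen = {}
    for d in death_list:
        if d.participant_id in seen:
            raise ValidationError(f"multiple death records for {d.participant_id!r}")
        seen[d.participant_id] = d.interval_end
    for pid, end in seen.items():
        if pid in alive.index:
            alive.loc[pid, [w for w in WAVES if w >= end]] = False

    if responded is None:
        responded = pd.DataFrame(True, index=participants, columns=list(WAVES))
    else:
        responded = responded.reindex(index=participants, columns=list(WAVES)).fillna(False)
    responded = responded & alive  # the dead never respond at later waves
    return StatusTable(enduring, dep_anx, alive, responded.astype(bool))


def select_analysis_sample(
    status: StatusTable, ffq_complete: pd.Series
) -> tuple[pd.Index, dict[str, int]]:
    """Apply the eligibility flow; returns (eligible ids, exclusion counts).

    Eligible participants responded at S3, responded at >= 1 wave of S4-S8,
    have complete dietary data, and reported none of the five enduring
    conditions at or before S3.  Counts are tallied sequentially for a flow
    diagram.
    """
    ffq_complete = ffq_complete.copy()
    ffq_complete.index = ffq_complete.index.astype(str)
    ffq_complete = ffq_complete.reindex(status.participants).fillna(False).astype(bool)

    counts = {"initial": int(len(status.participants))}
    mask = status.responded[BASELINE_WAVE].copy()
    counts["excluded_not_responded_s3"] = int((~mask).sum())

    follow_up = status.responded[list(OUTCOME_WAVES)].any(axis=1)
    counts["excluded_no_follow_up"] = int((mask & ~follow_up).sum())
    mask &= follow_up

    counts["excluded_ffq_incomplete"] = int((mask & ~ffq_complete).sum())
    mask &= ffq_complete

    ncd_at_baseline = pd.Series(False, index=status.participants)
    for cond in ENDURING_CONDITIONS:
        ncd_at_baseline |= status.enduring[cond][BASELINE_WAVE] > 0
    counts["excluded_ncd_at_or_before_s3"] = int((mask & ncd_at_baseline).sum())
    mask &= ~ncd_at_baseline

    counts["eligible"] = int(mask.sum())
    return status.participants[mask], counts


def _check_wave(wave: int) -> None:
    if wave not in OUTCOME_WAVES:
        raise ValidationError(f"outcome wave {wave} outside S4..S8")


def incident_outcome(
    status: StatusTable, wave: int, condition: str, sample: pd.Index
) -> pd.Series:
    """Cumulative incident 0/1 outcome at a wave among that wave's
    respondents in the analysis sample (all were condition-free at S3 for
    the enduring conditions; dep_anx is current status)."""
    _check_wave(wave)
    if condition not in CONDITION_GROUPS:
        raise ValidationError(f"unknown outcome condition {condition!r}")
    respondents = status.participants[(status.responded[wave]) & status.participants.isin(sample)]
    return status.status_at(condition, wave).loc[respondents].astype(int)


def multimorbidity_outcome(status: StatusTable, wave: int, sample: pd.Index) -> pd.Series:
    """1 if two or more of the six condition groups co-exist at the wave
    (depression and/or anxiety counts as a single group)."""
    _check_wave(wave)
    respondents = status.participants[(status.responded[wave]) & status.participants.isin(sample)]
    return (status.group_count(wave).loc[respondents] >= 2).astype(int)


def mortality_outcome(
    deaths: Iterable[DeathRecord],
    wave: int,
    sample: pd.Index,
    scope: str = "all_women",
    status: StatusTable | None = None,
) -> pd.Series:
    """Incident all-cause mortality at a wave.

    Outcome is 1 for deaths in the interval ending at ``wave``; the
    denominator is the sample minus deaths from earlier intervals.  With
    ``scope="ncd_subset"`` the denominator is further restricted to women
    who ever had any NCD (requires ``status``).
    """
    _check_wave(wave)
    if scope not in ("all_women", "ncd_subset"):
        raise ValidationError(f"unknown mortality scope {scope!r}")
    interval_end = {}
    for d in deaths:
        if d.participant_id in interval_end:
            raise ValidationError(f"multiple death records for {d.participant_id!r}")
        interval_end[d.participant_id] = d.interval_end

    sample = pd.Index([str(p) for p in sample])
    ends = pd.Series({p: interval_end.get(p, np.inf) for p in sample})
    denominator = sample[ends >= wave]
    if scope == "ncd_subset":
        if status is None:
            raise ValueError("ncd_subset mortality requires a StatusTable")
        ever = status.ever_any_ncd()
        denominator = denominator[ever.reindex(denominator).fillna(0).astype(bool)]
    return (ends.loc[denominator] == wave).astype(int)
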