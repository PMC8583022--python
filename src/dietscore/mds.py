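"""Mediterranean Diet Score (MDS) scoring.

Nine binary components summing to 0 (minimum adherence) - 9 (maximum
adherence).  Six beneficial components (vegetables, legumes, fruits,
cereals, fish, lipid ratio) score 1 at or above the sample median and 0
below; two detrimental components (red and processed meat, dairy) score 1
below the sample median and 0 at or above; alcohol scores 1 inside the
moderate range of 5-25 g/day inclusive.

The lipid ratio is (MUFA + PUFA) / saturated fat per participant.  Because
six of the cut points are sample medians, scoring requires a
:class:`MedianReference` computed on the same analysis sample; the median
is the conventional interpolated 50th percentile.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence  # noqa: F401 - public signature

import numpy as np
import pandas as pd

from .records import ComponentScore, DQIScore, IntakeRecord, ValidationError, records_to_frame

BENEFICIAL = ("veg_g", "legume_g", "fruit_g", "cereal_g", "fish_g", "lipid_ratio")
DETRIMENTAL = ("red_processed_meat_g", "dairy_g")

#: moderate-alcohol window in g/day, closed at both ends
ALCOHOL_RANGE = (5.0, 25.0)


@dataclass(frozen=True)
class MedianReference:
    """Sample medians anchoring the six beneficial and two detrimental
    MDS components, with the sample size they were computed from."""

    veg_g: float
    legume_g: float
    fruit_g: float
    cereal_g: float
    fish_g: float
    lipid_ratio: float
    red_processed_meat_g: float
    dairy_g: float
    sample_n: int

    def as_dict(self) -> dict:
        return asdict(self)


def lipid_ratio(mufa_g, pufa_g, sfa_g, participant_id=None):
    """(MUFA + PUFA) / SFA; saturated fat must be strictly positive."""
    sfa = np.asarray(sfa_g, dtype=float)
    if np.any(sfa <= 0):
        who = f" (participant {participant_id!r})" if participant_id is not None else ""
        raise ValidationError(f"sfa_g must be > 0 for the MDS lipid ratio{who}")
    ratio = (np.asarray(mufa_g, dtype=float) + np.asarray(pufa_g, dtype=float)) / sfa
    return float(ratio) if np.isscalar(mufa_g) else ratio


def _with_lipid_ratio(df: pd.DataFrame) -> pd.DataFrame:
    bad = df["sfa_g"] <= 0
    if bad.any():
        who = df.loc[bad, "participant_id"].iloc[0]
        raise ValidationError(f"sfa_g must be > 0 for the MDS lipid ratio (participant {who!r})")
    df = df.copy()
    df["lipid_ratio"] = (df["mufa_g"] + df["pufa_g"]) / df["sfa_g"]
    return df


def compute_mds_reference(sample: Sequence[IntakeRecord] | pd.DataFrame) -> MedianReference:
    """Interpolated 50th-percentile medians over the analysis sample
    (>= 2 records) for every median-anchored MDS component."""
    df = sample if isinstance(sample, pd.DataFrame) else records_to_frame(sample)
    if len(df) < 2:
        raise ValidationError(f"MDS reference needs >= 2 records, got {len(df)}")
    df = _with_lipid_ratio(df)
    medians = {col: float(np.median(df[col])) for col in BENEFICIAL + DETRIMENTAL}
    return MedianReference(sample_n=len(df), **medians)


def score_mds(intake: IntakeRecord, ref: MedianReference) -> DQIScore:
    """Score one participant against a sample-median reference."""
    if ref is None:
        raise ValueError("score_mds requires a MedianReference from the analysis sample")
    ratio = lipid_ratio(intake.mufa_g, intake.pufa_g, intake.sfa_g, intake.participant_id)
    values = {col: getattr(intake, col) for col in BENEFICIAL if col != "lipid_ratio"}
    values["lipid_ratio"] = ratio
    components = [
        ComponentScore(col, 1.0 if values[col] >= getattr(ref, col) else 0.0, 1.0)
        for col in BENEFICIAL
    ]
    components += [
        ComponentScore(col, 1.0 if getattr(intake, col) < getattr(ref, col) else 0.0, 1.0)
        for col in DETRIMENTAL
    ]
    lo, hi = ALCOHOL_RANGE
    components.append(ComponentScore("alcohol", 1.0 if lo <= intake.alcohol_g <= hi else 0.0, 1.0))
    total = float(sum(c.points for c in components))
    return DQIScore("MDS", total, tuple(components))


def score_mds_frame(df: pd.DataFrame, ref: MedianReference | None = None) -> pd.DataFrame:
    """Vectorised MDS over a wide intake table; computes the median
    reference from the same table when ``ref`` is None."""
    if ref is None:
        ref = compute_mds_reference(df)
    df = _with_lipid_ratio(df)
    out = pd.DataFrame(index=df.index)
    for col in BENEFICIAL:
        out[col] = (df[col] >= getattr(ref, col)).astype(float)
    for col in DETRIMENTAL:
        out[col] = (df[col] < getattr(ref, col)).astype(float)
    lo, hi = ALCOHOL_RANGE
    out["alcohol"] = ((df["alcohol_g"] >= lo) & (df["alcohol_g"] <= hi)).astype(float)
    out["total"] = out.sum(axis=1)
    return out
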