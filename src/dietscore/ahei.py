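"""Alternative Healthy Eating Index 2010 (AHEI-2010) scoring.

Eleven components, each worth 0-10 points, total 0-110.  Six positive
components score proportionally between zero intake and a full-score
anchor (vegetables 5 servings/day, fruit 4 servings/day, whole grains
75 g/day, nuts and legumes 1 serving/day, long-chain omega-3 fats
250 mg/day, PUFA 2-10 % of energy).  Four negative components score 10 at
zero (or a low anchor) and 0 at/above a high anchor (SSBs and fruit juice
1 serving/day, red and processed meat 1.5 servings/day, trans fat
0.5-4 % of energy); sodium is scored by sample decile, 10 points in the
lowest decile down to 0 in the highest.  Alcohol rewards moderate intake
in women: 10 points at 0.5-1.5 drinks/day, 0 at >=2.5, with non-drinkers
scoring 2.5 (the published convention for abstainers, configurable).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .records import (
    ComponentScore,
    ConfigurationError,
    DQIScore,
    IntakeRecord,
    ValidationError,
    records_to_frame,
)

ArrayLike = Union[float, np.ndarray]

#: increasing components: (zero-score anchor, full-score anchor)
_INCREASING = {
    "vegetables": (0.0, 5.0),
    "fruit": (0.0, 4.0),
    "whole_grains": (0.0, 75.0),
    "nuts_legumes": (0.0, 1.0),
    "lc_omega3": (0.0, 250.0),
    "pufa": (2.0, 10.0),
}
#: decreasing components: (full-score anchor, zero-score anchor)
_DECREASING = {
    "ssb_juice": (0.0, 1.0),
    "red_processed_meat": (0.0, 1.5),
    "trans_fat": (0.5, 4.0),
}

#: component -> IntakeRecord field feeding it
COMPONENT_FIELDS = {
    "vegetables": "vegetable_serv",
    "fruit": "fruit_serv",
    "whole_grains": "wholegrain_g",
    "nuts_legumes": "nuts_legumes_serv",
    "lc_omega3": "lc_omega3_mg",
    "pufa": "pufa_pct_energy",
    "ssb_juice": "ssb_juice_serv",
    "red_processed_meat": "red_processed_meat_serv",
    "trans_fat": "transfat_pct_energy",
    "sodium": "sodium_mg",
    "alcohol": "drinks_per_day",
}

NONDRINKER_POINTS = 2.5


@dataclass(frozen=True)
class DecileReference:
    """Nine ordered sodium cut points (mg/day) splitting the analysis
    sample into ten equal-frequency bins."""

    cuts: tuple[float, ...]
    sample_n: int

    def __post_init__(self) -> None:
        if len(self.cuts) != 9:
            raise ValidationError(f"expected 9 sodium cut points, got {len(self.cuts)}")
        if any(b < a for a, b in zip(self.cuts, self.cuts[1:])):
            raise ValidationError("sodium decile cut points must be non-decreasing")

    def as_dict(self) -> dict:
        return {"cuts": list(self.cuts), "sample_n": self.sample_n}


def compute_sodium_deciles(sample: Sequence[IntakeRecord] | pd.DataFrame | np.ndarray) -> DecileReference:
    """Interpolated decile cut points of sodium over the analysis sample
    (>= 10 records)."""
    if isinstance(sample, pd.DataFrame):
        values = sample["sodium_mg"].to_numpy(dtype=float)
    elif isinstance(sample, np.ndarray):
        values = sample.astype(float)
    else:
        values = records_to_frame(sample)["sodium_mg"].to_numpy(dtype=float)
    if len(values) < 10:
        raise ValidationError(f"sodium deciles need >= 10 records, got {len(values)}")
    cuts = np.quantile(values, np.arange(1, 10) / 10.0)
    return DecileReference(tuple(float(c) for c in cuts), int(len(values)))


def sodium_decile(value: ArrayLike, ref: DecileReference) -> ArrayLike:
    """Decile (1..10) of a sodium value; values equal to a cut point fall
    in the lower decile, so an all-tied sample sits entirely in decile 1."""
    v = np.asarray(value, dtype=float)
    cuts = np.asarray(ref.cuts)
    d = 1 + (cuts[None, :] < v.reshape(-1, 1)).sum(axis=1)
    return int(d[0]) if np.isscalar(value) else d.reshape(v.shape)


def _alcohol_points(drinks: ArrayLike) -> ArrayLike:
    d = np.asarray(drinks, dtype=float)
    pts = np.select(
        [d == 0.0, d < 0.5, d <= 1.5, d < 2.5],
        [
            NONDRINKER_POINTS,
            NONDRINKER_POINTS + (10.0 - NONDRINKER_POINTS) * d / 0.5,
            10.0,
            10.0 * (2.5 - d),
        ],
        default=0.0,
    )
    return float(pts) if np.isscalar(drinks) else pts


def score_ahei_component(
    component_id: str, value: ArrayLike, ref: DecileReference | None = None
) -> ArrayLike:
    """Points (0-10) for one AHEI-2010 component; ``ref`` is required for
    sodium and ignored otherwise."""
    if np.any(np.asarray(value, dtype=float) < 0):
        raise ValidationError(f"negative value for AHEI component {component_id}")
    if component_id in _INCREASING:
        lo, hi = _INCREASING[component_id]
        v = np.asarray(value, dtype=float)
        pts = np.clip((v - lo) / (hi - lo), 0.0, 1.0) * 10.0
        return float(pts) if np.isscalar(value) else pts
    if component_id in _DECREASING:
        full, zero = _DECREASING[component_id]
        v = np.asarray(value, dtype=float)
        pts = np.clip((zero - v) / (zero - full), 0.0, 1.0) * 10.0
        return float(pts) if np.isscalar(value) else pts
    if component_id == "sodium":
        if ref is None:
            raise ValueError("AHEI sodium component requires a DecileReference")
        d = sodium_decile(value, ref)
        pts = 10.0 * (10.0 - np.asarray(d, dtype=float)) / 9.0
        return float(pts) if np.isscalar(value) else pts
    if component_id == "alcohol":
        return _alcohol_points(value)
    raise ConfigurationError(f"unknown AHEI component {component_id!r}")


COMPONENT_ORDER = (
    "vegetables",
    "fruit",
    "whole_grains",
    "nuts_legumes",
    "lc_omega3",
    "pufa",
    "ssb_juice",
    "red_processed_meat",
    "trans_fat",
    "sodium",
    "alcohol",
)


def score_ahei(intake: IntakeRecord, ref: DecileReference) -> DQIScore:
    """Full AHEI-2010 score for one participant (0-110)."""
    components = tuple(
        ComponentScore(
            name,
            score_ahei_component(name, getattr(intake, COMPONENT_FIELDS[name]), ref),
            10.0,
        )
        for name in COMPONENT_ORDER
    )
    total = float(sum(c.points for c in components))
    return DQIScore("AHEI-2010", total, components)


def score_ahei_frame(df: pd.DataFrame, ref: DecileReference | None = None) -> pd.DataFrame:
    """Vectorised AHEI-2010 over a wide intake table; computes the sodium
    decile reference from the same table when ``ref`` is None."""
    if ref is None:
        ref = compute_sodium_deciles(df)
    out = pd.DataFrame(index=df.index)
    for name in COMPONENT_ORDER:
        out[name] = score_ahei_component(name, df[COMPONENT_FIELDS[name]].to_numpy(), ref)
    out["total"] = out.sum(axis=1)
    return out
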