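"""Healthy Eating Index for Australian Adults (HEIFA-2013) scoring.

The index measures adherence to the 2013 Australian Dietary Guidelines on a
0-100 scale across 11 components: five core food groups (grains, vegetables,
fruit, dairy, meat/protein alternatives), discretionary foods, four nutrient
components (fats, sodium, sugar, alcohol), and water.  Grains, vegetables and
fruit each split 5 + 5 points between a servings sub-score and a second
sub-score (wholegrains for grains; variety for vegetables and fruit).

Core-food servings are scored in bands: full points at or beyond the
guideline serving target, zero strictly below the minimum serving bound, and
the range in between split into three equal bands worth 1/4, 1/2 and 3/4 of
the component maximum - the band structure printed for discretionary foods
(10 / 7.5 / 5 / 2.5 / 0 points for <2.5 / 2.5-3.4 / 3.5-4.4 / 4.5-5.4 / >=5.5
servings) generalised to every core component.
"""

from __future__ import annotations

from typing import Union

import numpy as np

from .records import (
    ComponentScore,
    ConfigurationError,
    DQIScore,
    IntakeRecord,
    ValidationError,
)

ArrayLike = Union[float, np.ndarray]

#: component -> (min servings, target servings, max points).  Score is 0
#: below the minimum, max at/above the target, banded in between.
CORE_FOOD_BANDS: dict[str, tuple[float, float, float]] = {
    "total_grains": (1.0, 6.0, 5.0),
    "wholegrains": (1.0, 3.0, 5.0),
    "vegetables_serv": (1.0, 5.0, 5.0),
    "fruit_serv": (0.5, 2.0, 5.0),
    "dairy": (0.5, 2.5, 10.0),
    "meat_protein": (0.5, 2.5, 10.0),
}

#: discretionary foods: full points below DISCRETIONARY_FULL servings,
#: zero at/above DISCRETIONARY_ZERO.
DISCRETIONARY_FULL = 2.5
DISCRETIONARY_ZERO = 5.5
DISCRETIONARY_MAX = 10.0


def _banded_increasing(servings: ArrayLike, lo: float, hi: float, max_points: float) -> ArrayLike:
    s = np.asarray(servings, dtype=float)
    step = (hi - lo) / 3.0
    k = np.clip(np.floor((s - lo) / step), 0, 2)
    pts = np.where(s < lo, 0.0, np.where(s >= hi, max_points, (k + 1) / 4.0 * max_points))
    return float(pts) if np.isscalar(servings) else pts


def _banded_decreasing(servings: ArrayLike, full: float, zero: float, max_points: float) -> ArrayLike:
    s = np.asarray(servings, dtype=float)
    step = (zero - full) / 3.0
    # distance above the full-score bound; bands are closed on the low-serving side
    k = np.clip(np.ceil((zero - s) / step) - 1, 0, 2)
    pts = np.where(s < full, max_points, np.where(s >= zero, 0.0, (k + 1) / 4.0 * max_points))
    return float(pts) if np.isscalar(servings) else pts


def score_heifa_core_food(component_id: str, servings: ArrayLike) -> ArrayLike:
    """Points for one core-food (or discretionary) component.

    Accepts a scalar or an array of servings/day; vectorises elementwise.
    """
    if np.any(np.asarray(servings, dtype=float) < 0):
        raise ValidationError(f"negative servings for {component_id}")
    if component_id == "discretionary":
        return _banded_decreasing(
            servings, DISCRETIONARY_FULL, DISCRETIONARY_ZERO, DISCRETIONARY_MAX
        )
    try:
        lo, hi, max_points = CORE_FOOD_BANDS[component_id]
    except KeyError:
        raise ConfigurationError(f"unknown HEIFA core-food component {component_id!r}") from None
    return _banded_increasing(servings, lo, hi, max_points)


#: vegetable variety groups -> minimum servings to earn the 1 point
_VEG_VARIETY_THRESHOLDS = {
    "veg_green_serv": 1.0,
    "veg_orange_serv": 1.0,
    "veg_cruciferous_serv": 1.0,
    "veg_tuber_bulb_serv": 1.0,
    "legume_serv": 0.5,
}


def score_heifa_variety(kind: str, intake: IntakeRecord) -> float:
    """Variety points: 1 point per vegetable group at/above its serving
    threshold (max 5); fruit scores 5 for >=2 distinct fruits, else 0."""
    if kind == "vegetable":
        return float(
            sum(
                1
                for field_name, thr in _VEG_VARIETY_THRESHOLDS.items()
                if getattr(intake, field_name) >= thr
            )
        )
    if kind == "fruit":
        return 5.0 if intake.fruit_variety_count >= 2 else 0.0
    raise ConfigurationError(f"unknown variety kind {kind!r}")


def satfat_points(pct_energy: ArrayLike) -> ArrayLike:
    """Saturated-fat sub-score: <=10 %E -> 5; (10, 12] -> 2.5; >12 -> 0."""
    p = np.asarray(pct_energy, dtype=float)
    pts = np.where(p <= 10.0, 5.0, np.where(p <= 12.0, 2.5, 0.0))
    return float(pts) if np.isscalar(pct_energy) else pts


def mufa_pufa_points(servings: ArrayLike) -> ArrayLike:
    """MUFA/PUFA sub-score: linear from 0 points at 0 servings to 5 at >=2."""
    s = np.asarray(servings, dtype=float)
    pts = np.clip(s / 2.0, 0.0, 1.0) * 5.0
    return float(pts) if np.isscalar(servings) else pts


def sodium_points(sodium_mg: ArrayLike) -> ArrayLike:
    """Sodium: <1610 mg -> 10; [1610, 2300] -> 5; >2300 -> 0."""
    v = np.asarray(sodium_mg, dtype=float)
    pts = np.where(v < 1610.0, 10.0, np.where(v <= 2300.0, 5.0, 0.0))
    return float(pts) if np.isscalar(sodium_mg) else pts


def sugar_points(pct_energy: ArrayLike) -> ArrayLike:
    """Total sugar: <5 %E -> 10; [5, 10] -> 5; >10 -> 0."""
    p = np.asarray(pct_energy, dtype=float)
    pts = np.where(p < 5.0, 10.0, np.where(p <= 10.0, 5.0, 0.0))
    return float(pts) if np.isscalar(pct_energy) else pts


def alcohol_points(std_drinks: ArrayLike) -> ArrayLike:
    """Alcohol: <=2 standard drinks (10 g each) -> 5; >2 -> 0."""
    d = np.asarray(std_drinks, dtype=float)
    pts = np.where(d <= 2.0, 5.0, 0.0)
    return float(pts) if np.isscalar(std_drinks) else pts


def score_heifa_nutrients(intake: IntakeRecord) -> tuple[ComponentScore, ...]:
    """The four nutrient components: fats (saturated-fat sub-score +
    MUFA/PUFA sub-score, max 10), sodium, sugar, and alcohol."""
    fats = satfat_points(intake.satfat_pct_energy) + mufa_pufa_points(intake.mufa_pufa_serv)
    return (
        ComponentScore("fats", fats, 10.0),
        ComponentScore("sodium", sodium_points(intake.sodium_mg), 10.0),
        ComponentScore("sugar", sugar_points(intake.total_sugar_pct_energy), 10.0),
        ComponentScore("alcohol", alcohol_points(intake.std_drinks), 5.0),
    )


def score_heifa_water(water_proportion: ArrayLike) -> ArrayLike:
    """Water points: 1 point per full 10% of beverage intake that is
    water/tea/herbal tea/coffee, capped at 5 (so >50% scores 5)."""
    p = np.asarray(water_proportion, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("water_proportion outside [0, 1]")
    pts = np.minimum(np.floor(p * 10.0), 5.0)
    return float(pts) if np.isscalar(water_proportion) else pts


def score_heifa(intake: IntakeRecord) -> DQIScore:
    """Full HEIFA-2013 score: 11 components summing to a 0-100 total."""
    grains = score_heifa_core_food("total_grains", intake.total_grain_serv) + score_heifa_core_food(
        "wholegrains", intake.wholegrain_serv
    )
    vegetables = score_heifa_core_food(
        "vegetables_serv", intake.vegetable_serv
    ) + score_heifa_variety("vegetable", intake)
    fruit = score_heifa_core_food("fruit_serv", intake.fruit_serv) + score_heifa_variety(
        "fruit", intake
    )
    components = (
        ComponentScore("grains", grains, 10.0),
        ComponentScore("vegetables", vegetables, 10.0),
        ComponentScore("fruit", fruit, 10.0),
        ComponentScore("dairy", score_heifa_core_food("dairy", intake.dairy_serv), 10.0),
        ComponentScore(
            "meat_protein", score_heifa_core_food("meat_protein", intake.meat_protein_serv), 10.0
        ),
        ComponentScore(
            "discretionary", score_heifa_core_food("discretionary", intake.discretionary_serv), 10.0
        ),
        *score_heifa_nutrients(intake),
        ComponentScore("water", score_heifa_water(intake.water_proportion), 5.0),
    )
    total = float(sum(c.points for c in components))
    return DQIScore("HEIFA-2013", total, components)


def score_heifa_frame(df) -> "pd.DataFrame":  # noqa: F821 - annotation only
    """Vectorised HEIFA-2013 over a wide intake table.

    Returns a DataFrame indexed like ``df`` with one column per component
    plus ``total``.
    """
    import pandas as pd

    variety_veg = sum(
        (df[field_name] >= thr).astype(float)
        for field_name, thr in _VEG_VARIETY_THRESHOLDS.items()
    )
    out = pd.DataFrame(index=df.index)
    out["grains"] = score_heifa_core_food(
        "total_grains", df["total_grain_serv"].to_numpy()
    ) + score_heifa_core_food("wholegrains", df["wholegrain_serv"].to_numpy())
    out["vegetables"] = (
        score_heifa_core_food("vegetables_serv", df["vegetable_serv"].to_numpy())
        + variety_veg.to_numpy()
    )
    out["fruit"] = score_heifa_core_food("fruit_serv", df["fruit_serv"].to_numpy()) + np.where(
        df["fruit_variety_count"].to_numpy() >= 2, 5.0, 0.0
    )
    out["dairy"] = score_heifa_core_food("dairy", df["dairy_serv"].to_numpy())
    out["meat_protein"] = score_heifa_core_food("meat_protein", df["meat_protein_serv"].to_numpy())
    out["discretionary"] = score_heifa_core_food(
        "discretionary", df["discretionary_serv"].to_numpy()
    )
    out["fats"] = satfat_points(df["satfat_pct_energy"].to_numpy()) + mufa_pufa_points(
        df["mufa_pufa_serv"].to_numpy()
    )
    out["sodium"] = sodium_points(df["sodium_mg"].to_numpy())
    out["sugar"] = sugar_points(df["total_sugar_pct_energy"].to_numpy())
    out["alcohol"] = alcohol_points(df["std_drinks"].to_numpy())
    out["water"] = score_heifa_water(df["water_proportion"].to_numpy())
    out["total"] = out.sum(axis=1)
    return out
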