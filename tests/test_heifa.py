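"""HEIFA-2013 scorer: printed bands, band-edge tables, and totals."""

import numpy as np
import pytest

import dietscore as ds
from dietscore.heifa import (
    CORE_FOOD_BANDS,
    alcohol_points,
    mufa_pufa_points,
    satfat_points,
    score_heifa_core_food,
    score_heifa_frame,
    score_heifa_nutrients,
    score_heifa_variety,
    score_heifa_water,
    sodium_points,
    sugar_points,
)
from dietscore.records import ConfigurationError, IntakeRecord, ValidationError, records_to_frame


@pytest.mark.parametrize(
    "servings, expected",
    [
        (0.0, 10.0), (2.4, 10.0),          # full score below 2.5
        (2.5, 7.5), (3.0, 7.5), (3.4, 7.5),
        (3.5, 5.0), (4.4, 5.0),
        (4.5, 2.5), (5.4, 2.5),
        (5.5, 0.0), (6.0, 0.0),
    ],
)
def test_discretionary_printed_bands(servings, expected):
    """The discretionary component reproduces the published band table."""
    assert score_heifa_core_food("discretionary", servings) == expected


def _band_oracle_increasing(servings, lo, hi, max_points):
    """Reference banding: zero below lo, max at/above hi, and the interior
    split into three equal bands scoring 1/4, 1/2, 3/4 (the discretionary
    band structure mirrored for beneficial components)."""
    if servings < lo:
        return 0.0
    if servings >= hi:
        return max_points
    width = (hi - lo) / 3.0
    for k in range(3):
        if servings < lo + (k + 1) * width:
            return (k + 1) / 4.0 * max_points
    return 0.75 * max_points


@pytest.mark.parametrize("component_id", sorted(CORE_FOOD_BANDS))
def test_core_food_bands_match_exhaustive_edge_table(component_id):
    """Every band edge (and a dense grid) matches the brute-force band
    oracle; scores are non-decreasing in servings."""
    lo, hi, max_points = CORE_FOOD_BANDS[component_id]
    width = (hi - lo) / 3.0
    boundaries = np.array([lo, lo + width, lo + 2 * width, hi])
    # probe just inside each band plus a dense grid, keeping clear of the
    # floating-point representation of the interior boundaries (band
    # membership within one ulp of a third-of-range edge is not defined
    # more finely than the serving data itself)
    edges = [0.0, lo / 2, lo + 1e-6, hi - 1e-6, hi, hi + 1.0]
    edges += [b + s * 1e-6 for b in boundaries for s in (-1, 1)]
    grid = np.concatenate([edges, np.linspace(0, hi + 2, 97)])
    grid = grid[np.abs(grid[:, None] - boundaries[None, :]).min(axis=1) > 1e-7]
    grid = np.concatenate([grid, [lo, hi]])  # exact anchors are well-defined
    pts = np.array([score_heifa_core_food(component_id, s) for s in grid])
    expected = np.array([_band_oracle_increasing(s, lo, hi, max_points) for s in grid])
    np.testing.assert_allclose(pts, expected)
    order = np.argsort(grid)
    assert (np.diff(pts[order]) >= 0).all()


def test_vegetables_midpoint_band():
    assert score_heifa_core_food("vegetables_serv", 3.0) == 2.5


def test_core_food_errors():
    with pytest.raises(ConfigurationError):
        score_heifa_core_food("not_a_component", 1.0)
    with pytest.raises(ValidationError):
        score_heifa_core_food("dairy", -0.5)


def test_vegetable_variety_counts_groups(profiles):
    rec = IntakeRecord(
        participant_id="v",
        veg_green_serv=1.2,
        veg_orange_serv=1.0,
        legume_serv=0.5,
    )
    assert score_heifa_variety("vegetable", rec) == 3.0
    assert score_heifa_variety("vegetable", IntakeRecord(participant_id="z")) == 0.0
    # sub-threshold servings earn nothing
    rec2 = IntakeRecord(participant_id="v2", veg_green_serv=0.9, legume_serv=0.4)
    assert score_heifa_variety("vegetable", rec2) == 0.0


@pytest.mark.parametrize("count, expected", [(0, 0.0), (1, 0.0), (2, 5.0), (3, 5.0)])
def test_fruit_variety_threshold(count, expected):
    rec = IntakeRecord(participant_id="f", fruit_variety_count=count)
    assert score_heifa_variety("fruit", rec) == expected


@pytest.mark.parametrize(
    "fn, value, expected",
    [
        (satfat_points, 9.0, 5.0),
        (satfat_points, 10.0, 5.0),
        (satfat_points, 11.0, 2.5),
        (satfat_points, 12.0, 2.5),
        (satfat_points, 12.1, 0.0),
        (mufa_pufa_points, 0.0, 0.0),
        (mufa_pufa_points, 1.0, 2.5),
        (mufa_pufa_points, 2.0, 5.0),
        (mufa_pufa_points, 3.0, 5.0),
        (sodium_points, 1500.0, 10.0),
        (sodium_points, 1609.9, 10.0),
        (sodium_points, 1610.0, 5.0),
        (sodium_points, 2300.0, 5.0),
        (sodium_points, 2301.0, 0.0),
        (sugar_points, 4.0, 10.0),
        (sugar_points, 5.0, 5.0),
        (sugar_points, 10.0, 5.0),
        (sugar_points, 11.0, 0.0),
        (alcohol_points, 2.0, 5.0),
        (alcohol_points, 2.1, 0.0),
    ],
)
def test_nutrient_cut_points(fn, value, expected):
    """Saturated fat, MUFA/PUFA, sodium, sugar and alcohol sub-scores at
    and around every printed cut point."""
    assert fn(value) == expected


def test_nutrient_components_assemble():
    rec = IntakeRecord(
        participant_id="n", satfat_pct_energy=13.0, mufa_pufa_serv=1.0,
        sodium_mg=2000.0, total_sugar_pct_energy=7.0, std_drinks=1.0,
    )
    by_name = {c.component_name: c for c in score_heifa_nutrients(rec)}
    assert by_name["fats"].points == 2.5  # 0 (satfat >12%) + 2.5 (1 serving)
    assert by_name["sodium"].points == 5.0
    assert by_name["sugar"].points == 5.0
    assert by_name["alcohol"].points == 5.0


@pytest.mark.parametrize(
    "proportion, expected",
    [(0.0, 0.0), (0.09, 0.0), (0.10, 1.0), (0.30, 3.0), (0.50, 5.0), (0.60, 5.0), (1.0, 5.0)],
)
def test_water_steps(proportion, expected):
    assert score_heifa_water(proportion) == expected


def test_water_rejects_out_of_range():
    with pytest.raises(ValidationError):
        score_heifa_water(1.2)


def test_maximal_profile_scores_100(profiles):
    score = ds.score_heifa(profiles["heifa_max"])
    assert score.total == 100.0
    assert len(score.components) == 11
    maxima = {c.component_name: c.max_points for c in score.components}
    assert maxima["alcohol"] == 5.0 and maxima["water"] == 5.0
    assert sum(maxima.values()) == 100.0


def test_floor_profile_scores_0(profiles):
    assert ds.score_heifa(profiles["heifa_min"]).total == 0.0


def test_frame_scoring_matches_per_record(small_cohort):
    df = small_cohort.intake.head(50)
    frame_totals = score_heifa_frame(df)["total"].to_numpy()
    from dietscore.records import frame_to_records

    rec_totals = np.array([ds.score_heifa(r).total for r in frame_to_records(df)])
    np.testing.assert_allclose(frame_totals, rec_totals, atol=1e-12)
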