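"""Packaged worked-example tables and the synthetic dish generator."""

import numpy as np
import pytest

from npmdj import (
    DishCategory,
    NutrientVector,
    SyntheticDishSpec,
    ValidationError,
    classify_dish,
    generate_synthetic_catalog,
    generate_synthetic_dishes,
    intended_category,
    load_fixtures,
    score_dish,
    soup_scenario,
)
from npmdj.fixtures import ARCHETYPES


# --------------------------------------------------------------------------
# Fixture tables
# --------------------------------------------------------------------------

def test_catalog_has_105_dishes_in_the_published_split(t4_rows):
    assert len(t4_rows) == 105
    counts = {}
    for row in t4_rows:
        counts[row.category] = counts.get(row.category, 0) + 1
    assert counts == {
        DishCategory.STAPLE: 20, DishCategory.SIDE: 34, DishCategory.MAIN: 21,
        DishCategory.MIXED: 12, DishCategory.MIXED_WITH_STAPLE: 18,
    }


def test_soup_table_has_six_dishes_by_three_scenarios(t3_rows):
    assert len(t3_rows) == 18
    dishes = {r.dish_id.split(":")[0] for r in t3_rows}
    assert len(dishes) == 6
    scenarios = {r.scenario for r in t3_rows}
    assert scenarios == {"left_all", "half", "all"}


def test_crab_omelet_ramen_all_soup_final_score(t3_rows):
    (row,) = [r for r in t3_rows if r.dish_id == "tenshin:all"]
    assert row.final_score == 37
    assert row.baseline == 45


def test_every_rating_glyph_parses(t4_rows):
    stars = [row.stars.stars for row in t4_rows]
    assert all(0.5 <= s <= 5.0 for s in stars)


def test_suspected_rice_weight_typo_is_flagged_not_corrected(t4_rows):
    flagged = [r for r in t4_rows if r.flagged]
    assert len(flagged) == 1
    row = flagged[0]
    # the printed (suspect) weight is stored verbatim
    assert "middle, 150 g" in row.name
    assert row.food_weight_excl_water_g == 100


def test_unknown_table_rejected():
    with pytest.raises(ValidationError):
        load_fixtures("T9")


# --------------------------------------------------------------------------
# Soup scenarios
# --------------------------------------------------------------------------

def _soup_pair(t3_rows, dish_id):
    rows = {r.scenario: r for r in t3_rows if r.dish_id.startswith(dish_id + ":")}
    return rows["left_all"], rows["half"], rows["all"]


SOUP_NUTRIENTS = NutrientVector(50, 0.5, 1.0, 1500, 2.0, 0.2)


def test_soup_fraction_zero_and_one_are_the_endpoints(t3_rows):
    left, _, _ = _soup_pair(t3_rows, "udon")
    base = left.to_dish_record()
    untouched = soup_scenario(base, SOUP_NUTRIENTS, 26, 185, 0.0)
    assert untouched.nutrients == base.nutrients
    assert untouched.food_weight_excl_water_g == base.food_weight_excl_water_g
    full = soup_scenario(base, SOUP_NUTRIENTS, 26, 185, 1.0)
    assert full.nutrients.sodium_mg == pytest.approx(base.nutrients.sodium_mg + 1500)
    assert full.food_weight_excl_water_g == pytest.approx(base.food_weight_excl_water_g + 26)


def test_soup_fraction_outside_unit_interval_rejected(t3_rows):
    base = _soup_pair(t3_rows, "udon")[0].to_dish_record()
    with pytest.raises(ValidationError):
        soup_scenario(base, SOUP_NUTRIENTS, 26, 185, 1.2)


@pytest.mark.parametrize("dish_id,half_weight", [
    ("udon", 345), ("tempura_udon", 388), ("ramen", 262),
    ("roast_pork_ramen", 323), ("tenshin", 464),
])
def test_half_soup_food_weight_is_the_linear_midpoint(t3_rows, dish_id, half_weight):
    """For the soup-in-bowl noodles the published half-consumed food weight
    is exactly the midpoint of the left-all and all-consumed rows."""
    left, half, full = _soup_pair(t3_rows, dish_id)
    base = left.to_dish_record()
    mixed = soup_scenario(
        base, SOUP_NUTRIENTS,
        soup_food_weight_g=full.food_weight_excl_water_g - left.food_weight_excl_water_g,
        soup_total_weight_g=full.total_food_weight_g - left.total_food_weight_g,
        fraction=0.5,
    )
    assert mixed.food_weight_excl_water_g == pytest.approx(half_weight)
    assert mixed.food_weight_excl_water_g == pytest.approx(half.food_weight_excl_water_g)
    # total weights in the published rows carry independent per-scenario
    # rounding: the linear model lands within a few grams
    assert mixed.total_food_weight_g == pytest.approx(half.total_food_weight_g, abs=3)


def test_dipped_soba_half_scenario_is_not_linear(t3_rows):
    """Cold soba is dipped, not served in soup: its published half-consumed
    food weight (321 g) is below the linear midpoint (327 g)."""
    left, half, full = _soup_pair(t3_rows, "zaru_soba")
    midpoint = (left.food_weight_excl_water_g + full.food_weight_excl_water_g) / 2
    assert midpoint == pytest.approx(327)
    assert half.food_weight_excl_water_g == 321 != midpoint


# --------------------------------------------------------------------------
# Synthetic dishes
# --------------------------------------------------------------------------

def test_generator_is_deterministic_under_a_fixed_seed():
    spec = SyntheticDishSpec("staple", 50, 7)
    assert generate_synthetic_dishes(spec) == generate_synthetic_dishes(spec)


def test_generator_rejects_empty_and_unknown_requests():
    with pytest.raises(ValidationError):
        SyntheticDishSpec("staple", 0, 1)
    with pytest.raises(ValidationError):
        generate_synthetic_dishes(SyntheticDishSpec("dessert", 5, 1))


def test_side_archetype_classifies_as_side():
    dishes = generate_synthetic_dishes(SyntheticDishSpec("side", 100, 1))
    hits = sum(classify_dish(d) is DishCategory.SIDE for d in dishes)
    assert hits >= 99


def test_every_archetype_round_trips_through_the_classifier():
    for archetype in ARCHETYPES:
        dishes = generate_synthetic_dishes(SyntheticDishSpec(archetype, 40, 11))
        hits = sum(classify_dish(d) is intended_category(d.dish_id)
                   for d in dishes)
        assert hits >= 39, archetype


def test_catalog_mix_matches_reference_composition():
    catalog = generate_synthetic_catalog(3)
    assert len(catalog) == 105
    counts = {}
    for dish in catalog:
        counts[intended_category(dish.dish_id)] = counts.get(
            intended_category(dish.dish_id), 0) + 1
    assert counts[DishCategory.SIDE] == 34


def test_synthetic_component_medians_near_reference_catalog(config):
    """Smoke check of the generator's calibration: scoring a synthetic
    catalog mixed in the reference proportions lands the overall component
    medians within one point of the published catalog medians."""
    catalog = generate_synthetic_catalog(1)
    pts = np.array([
        (r.points.energy_pts, r.points.satfat_pts, r.points.sugars_pts,
         r.points.v_pts, r.points.protein_pts, r.points.fiber_pts)
        for r in (score_dish(d, config) for d in catalog)
    ])
    medians = np.median(pts, axis=0)
    targets = (1, 2, 1, 0, 0, 3)
    for name, got, want in zip(
            ("energy", "satfat", "sugars", "v", "protein", "fiber"),
            medians, targets):
        assert abs(got - want) <= 1, (name, got, want)
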