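"""Band lookup, fvnl, the protein cap, and score aggregation."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from npmdj import (
    BandTable,
    ComponentPoints,
    DishRecord,
    FvnlInfo,
    IngredientEntry,
    NutrientVector,
    ValidationError,
    apply_protein_cap,
    band_points,
    compute_fvnl,
    restricted_points,
    score_dish,
    v_points,
)


def brute_force_linear_points(amount, width, max_points):
    """Independent oracle: count the multiples of ``width`` strictly below
    ``amount`` one by one."""
    k = 0
    while k < max_points and amount > (k + 1) * width:
        k += 1
    return k


# --------------------------------------------------------------------------
# band_points
# --------------------------------------------------------------------------

def test_band_points_zero_below_first_threshold(config):
    for component in ("energy", "satfat", "sugars", "sodium", "protein", "fiber"):
        assert band_points(config.band_table(component, energy_kcal=500), 0.0) == 0


def test_band_thresholds_must_be_strictly_exceeded(config):
    sodium = config.band_table("sodium")
    # exactly on the first threshold (3.75% of 2756 mg = 103.35 mg): no point yet
    assert band_points(sodium, 103.35) == 0
    assert band_points(sodium, 103.36) == 1
    assert band_points(sodium, 207.0) == 2  # floor(207 / 103.35)


def test_energy_band_matches_rice_dish(config):
    # a 150 g rice dish at ~234 kcal sits in the 2-point band (width 82.5)
    assert band_points(config.band_table("energy"), 234.0) == 2


def test_linear_tables_agree_with_brute_force_oracle(config):
    import numpy as np
    rng = np.random.default_rng(0)
    for component, width, max_points in (("energy", 82.5, 9), ("sodium", 103.35, 30)):
        table = config.band_table(component)
        hi = width * (max_points + 3)
        for amount in rng.uniform(0, hi, size=500):
            assert band_points(table, amount) == brute_force_linear_points(
                amount, width, max_points), (component, amount)


def test_negative_amount_rejected(config):
    with pytest.raises(ValidationError):
        band_points(config.band_table("energy"), -1.0)


@given(
    thresholds=st.lists(
        st.floats(min_value=0.01, max_value=1e4, allow_nan=False),
        min_size=1, max_size=12, unique=True,
    ).map(sorted),
    amounts=st.tuples(st.floats(min_value=0, max_value=2e4),
                      st.floats(min_value=0, max_value=2e4)),
)
def test_band_lookup_is_monotone_for_every_valid_table(thresholds, amounts):
    table = BandTable(component="energy", unit="kcal",
                      thresholds=tuple(thresholds), max_points=len(thresholds))
    lo, hi = sorted(amounts)
    assert band_points(table, lo) <= band_points(table, hi)


# --------------------------------------------------------------------------
# fvnl and V points
# --------------------------------------------------------------------------

ZERO = NutrientVector(0, 0, 0, 0, 0, 0)


def _dish(ingredients, excl_water, total):
    return DishRecord("d", "d", ZERO, excl_water, total,
                      ingredients=tuple(ingredients))


def test_fvnl_all_vegetable_is_one():
    dish = _dish([IngredientEntry("tomato", 100, "vegetable")], 100, 100)
    assert compute_fvnl(dish).fraction == pytest.approx(1.0)


def test_fvnl_excludes_potatoes():
    dish = _dish([IngredientEntry("potato", 100, "potato")], 100, 100)
    assert compute_fvnl(dish).fraction == pytest.approx(0.0)


def test_fvnl_excludes_water_from_denominator():
    dish = _dish([
        IngredientEntry("veg", 50, "vegetable"),
        IngredientEntry("meat", 50, "meat"),
        IngredientEntry("stock", 200, "water_stock"),
    ], 100, 300)
    assert compute_fvnl(dish).fraction == pytest.approx(0.5)


@pytest.mark.parametrize("fraction,expected", [
    (0.0, 0),
    (0.39, 0),   # hard zero below 40% fvnl
    (1.0, 7),    # a 100% vegetable dish tops out at 7 V points
])
def test_v_points(config, fraction, expected):
    assert v_points(FvnlInfo.from_fraction(fraction), config) == expected


# --------------------------------------------------------------------------
# restricted points
# --------------------------------------------------------------------------

def test_all_zero_vector_scores_nothing(config):
    assert restricted_points(ZERO, config) == (0, 0, 0, 0)


def test_energy_relative_bands_use_dish_energy(config):
    # at 600 kcal the satfat anchor is 7% of 600 kcal / 9 kcal per g
    table = config.band_table("satfat", energy_kcal=600)
    assert table.thresholds[0] == pytest.approx(0.07 * 600 / 9)
    # with zero dish energy the anchors degenerate: fall back to the
    # reference energy intake
    fallback = config.band_table("satfat", energy_kcal=0)
    assert fallback.thresholds[0] == pytest.approx(0.07 * 2200 / 9)


def test_vector_calibrated_to_crab_omelet_ramen_row(config):
    """A nutrient vector whose banded points equal the highest-scoring
    catalog row (7, 7, 1, 30): energy in the 7-point band, saturated fat
    and sugars in their energy-relative bands, sodium beyond the 30-point
    cap."""
    nutrients = NutrientVector(
        energy_kcal=600, satfat_g=35, sugars_g=20, sodium_mg=3200,
        protein_g=0, fiber_g=0,
    )
    assert restricted_points(nutrients, config) == (7, 7, 1, 30)


# --------------------------------------------------------------------------
# protein cap
# --------------------------------------------------------------------------

@pytest.mark.parametrize("baseline,v,raw,expected", [
    (10, 0, 4, 4),   # below the 13-point baseline cap: protein retained
    (28, 0, 4, 0),   # at/above 13 without 5 V points: protein zeroed
    (13, 5, 7, 7),   # five or more V points exempt the dish
    (12, 0, 9, 9),
])
def test_protein_cap_rule(config, baseline, v, raw, expected):
    assert apply_protein_cap(baseline, v, raw, config) == expected


# --------------------------------------------------------------------------
# score_dish
# --------------------------------------------------------------------------

def _precomputed(e, sf, su, na, v, p, f):
    return ComponentPoints(energy_pts=e, satfat_pts=sf, sugars_pts=su,
                           sodium_pts=na, v_pts=v, protein_pts_raw=p,
                           protein_pts=p, fiber_pts=f)


def test_score_dish_fixture_mode_examples(config):
    # crab-omelet ramen, all soup consumed: baseline 45, final 37
    res = score_dish(None, config, precomputed=_precomputed(7, 7, 1, 30, 0, 0, 8))
    assert (res.baseline, res.final_score) == (45, 37)
    # pork cutlet with sauce: baseline 23, no modification, final 23
    res = score_dish(None, config, precomputed=_precomputed(4, 13, 1, 5, 0, 0, 0))
    assert (res.baseline, res.final_score) == (23, 23)
    # all zeros
    res = score_dish(None, config, precomputed=_precomputed(0, 0, 0, 0, 0, 0, 0))
    assert res.final_score == 0


def test_score_dish_reapplies_cap_to_raw_protein(config):
    res = score_dish(None, config, precomputed=_precomputed(3, 0, 0, 24, 0, 4, 8))
    assert res.points.protein_pts == 0
    assert res.cap_applied
    assert res.final_score == 27 - 8


def test_score_dish_requires_some_input(config):
    with pytest.raises(ValidationError):
        score_dish(None, config)


def test_score_dish_from_nutrients_end_to_end(config):
    dish = DishRecord(
        "salad", "vegetable salad",
        NutrientVector(60, 0.2, 1.0, 250, 1.5, 2.0),
        100, 100,
        ingredients=(IngredientEntry("greens", 100, "vegetable",
                                     is_main_ingredient=True),),
    )
    res = score_dish(dish, config)
    assert res.points.v_pts == 7          # 100% fvnl
    assert res.points.sodium_pts == 2     # 250 / 103.35
    assert res.points.fiber_pts == 2      # 2.0 / 0.7125
    assert res.final_score == res.baseline - res.modification


def test_cap_discontinuity_jump_exceeds_band_increment(config):
    """Raising sodium by one band across the 13-point baseline can raise
    the final score by the band point *plus* the whole forfeited protein
    score (the noodle-soup effect)."""
    def result(sodium_mg):
        dish = DishRecord(
            "noodle", "noodle dish",
            NutrientVector(300, 0, 0, sodium_mg, 13.0, 4.0),
            300, 300,
        )
        return score_dish(dish, config, fvnl=FvnlInfo.from_fraction(0.0))

    below = result(103.35 * 9 + 1)    # sodium 9 pts, baseline 12
    above = result(103.35 * 10 + 1)   # sodium 10 pts, baseline 13
    assert below.baseline == 12 and above.baseline == 13
    assert below.points.protein_pts == above.points.protein_pts_raw > 0
    assert above.points.protein_pts == 0 and above.cap_applied
    jump = above.final_score - below.final_score
    assert jump == 1 + below.points.protein_pts
    assert jump > 1


def test_final_score_monotone_in_recommended_components(config):
    base = score_dish(None, config, precomputed=_precomputed(3, 1, 1, 4, 0, 2, 3))
    more_fiber = score_dish(None, config, precomputed=_precomputed(3, 1, 1, 4, 0, 2, 5))
    more_v = score_dish(None, config, precomputed=_precomputed(3, 1, 1, 4, 2, 2, 3))
    assert more_fiber.final_score <= base.final_score
    assert more_v.final_score <= base.final_score
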