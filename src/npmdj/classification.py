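"""Two-step dish categorization.

Step 1 assigns a category outright when a single food-group family
contributes strictly more than two-thirds of the cooked food weight
(excluding water and stock): grains make a staple, the vegetable family
(including potatoes) a side, and protein sources a main.  Dishes matching
no step-1 rule are split by their serving (SV) tallies in step 2: a dish
with under half a staple serving but at least half a serving of both a
main and a side is a *mixed dish*; a dish with at least half a staple
serving plus at least half a serving of a main or a side is a *mixed dish
with staple*.  Anything else remains unclassified — the classifier never
guesses.

Step-1 membership is a weight *fraction*, so it is invariant under uniform
scaling of a recipe; the step-2 SV tallies are absolute amounts and scale
with the recipe.
"""

from __future__ import annotations

from typing import Optional

from .types import (
    GRAIN_GROUPS,
    PROTEIN_GROUPS,
    SIDE_GROUPS,
    DishCategory,
    DishRecord,
    ServingCounts,
    ValidationError,
)

#: Grams of carbohydrate from the main grain ingredient per staple serving.
CARB_G_PER_STAPLE_SV = 40.0
#: Grams of main side-group ingredient per side serving.
WEIGHT_G_PER_SIDE_SV = 70.0
#: Grams of protein from the main protein ingredient per main serving.
PROTEIN_G_PER_MAIN_SV = 6.0

#: Step-1 weight share that must be strictly exceeded.
STEP1_FRACTION = 2.0 / 3.0
#: Step-2 serving count that must be met or exceeded.
STEP2_MIN_SV = 0.5


def compute_serving_counts(dish: DishRecord) -> ServingCounts:
    """Tally staple/side/main servings from the dish's main ingredients."""
    if not dish.ingredients:
        raise ValidationError(
            f"dish {dish.dish_id!r}: serving counts require an ingredient list"
        )
    staple_carb = sum(
        ing.carbohydrate_g for ing in dish.ingredients
        if ing.is_main_ingredient and ing.group in GRAIN_GROUPS
    )
    side_weight = sum(
        ing.cooked_weight_g for ing in dish.ingredients
        if ing.is_main_ingredient and ing.group in SIDE_GROUPS
    )
    main_protein = sum(
        ing.protein_g for ing in dish.ingredients
        if ing.is_main_ingredient and ing.group in PROTEIN_GROUPS
    )
    return ServingCounts(
        staple_sv=staple_carb / CARB_G_PER_STAPLE_SV,
        side_sv=side_weight / WEIGHT_G_PER_SIDE_SV,
        main_sv=main_protein / PROTEIN_G_PER_MAIN_SV,
    )


def classify_step1(dish: DishRecord) -> Optional[DishCategory]:
    """Category by the strict two-thirds weight rule, or ``None`` for no match.

    With strictly-greater-than comparison at exactly 2/3, at most one group
    family can match (two shares each above 2/3 would sum past 1).
    """
    if not dish.ingredients:
        raise ValidationError(
            f"dish {dish.dish_id!r}: step-1 classification requires ingredients"
        )
    total = dish.food_weight_excl_water_g
    if total <= 0:
        raise ValidationError(
            f"dish {dish.dish_id!r}: food weight excluding water must be > 0"
        )
    for groups, category in (
        (GRAIN_GROUPS, DishCategory.STAPLE),
        (SIDE_GROUPS, DishCategory.SIDE),
        (PROTEIN_GROUPS, DishCategory.MAIN),
    ):
        weight = dish.ingredient_weight(groups)
        # strict "> 2/3" without float division: weight/total > 2/3
        if 3.0 * weight > 2.0 * total:
            return category
    return None


def classify_step2(sv: ServingCounts) -> DishCategory:
    """Category for step-1 non-matches, from the serving tallies."""
    if sv.staple_sv < STEP2_MIN_SV and sv.side_sv >= STEP2_MIN_SV and sv.main_sv >= STEP2_MIN_SV:
        return DishCategory.MIXED
    if sv.staple_sv >= STEP2_MIN_SV and (sv.side_sv >= STEP2_MIN_SV or sv.main_sv >= STEP2_MIN_SV):
        return DishCategory.MIXED_WITH_STAPLE
    return DishCategory.UNCLASSIFIED


def classify_dish(dish: DishRecord) -> DishCategory:
    """Full categorization: an explicit override wins, else step 1 then step 2."""
    if dish.category_override is not None:
        return dish.category_override
    if not dish.ingredients:
        raise ValidationError(
            f"dish {dish.dish_id!r}: classification needs ingredients or a "
            "category_override"
        )
    step1 = classify_step1(dish)
    if step1 is not None:
        return step1
    return classify_step2(compute_serving_counts(dish))
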