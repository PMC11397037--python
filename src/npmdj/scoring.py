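"""Component point evaluation, the protein cap, and score aggregation.

Each restricted component (energy, saturated fat, total sugars, sodium)
earns points through a banded lookup: a band threshold must be strictly
exceeded to earn its point, so an amount sitting exactly on the first
threshold still scores zero.  Saturated-fat and sugars bands are anchored
to the dish's own energy (7%E and 10%E respectively), so their effective
gram thresholds are recomputed per dish before lookup.

Recommended components offset the baseline: V points reward the fvnl
weight fraction (zero below 40%), protein and fiber points reward absolute
gram amounts.  The protein cap then zeroes the protein score for dishes
with a baseline of 13 points or more unless they hold at least five V
points, and

    final score = baseline - (V + protein + fiber).

The cap makes the final score discontinuous: a dish whose baseline crosses
13 can lose its entire protein offset at once, jumping the final score by
far more than the one-point band increment (noodle-soup scenarios swing by
up to 22 points this way).
"""

from __future__ import annotations

import math
from typing import Optional, Tuple

from .types import (
    FVNL_GROUPS,
    BandTable,
    ComponentPoints,
    DishRecord,
    FvnlInfo,
    ModelConfig,
    NutrientVector,
    ScoreResult,
    ValidationError,
)


def band_points(table: BandTable, amount: float) -> int:
    """Points earned by ``amount``: thresholds strictly exceeded, clipped.

    Zero below (or exactly on) the first threshold; monotone
    non-decreasing in the amount.
    """
    if not math.isfinite(amount) or amount < 0:
        raise ValidationError(
            f"{table.component}: amount must be finite and >= 0, got {amount!r}"
        )
    exceeded = sum(1 for t in table.thresholds if amount > t)
    return min(exceeded, table.max_points)


def compute_fvnl(dish: DishRecord) -> FvnlInfo:
    """fvnl weight fraction: cooked fruits, vegetables, nuts, legumes,
    seaweed, seeds and mushrooms over the cooked food weight excluding
    water and stock.  Potatoes are excluded from the numerator."""
    if not dish.ingredients:
        raise ValidationError(
            f"dish {dish.dish_id!r}: fvnl requires an ingredient list"
        )
    if dish.food_weight_excl_water_g <= 0:
        raise ValidationError(
            f"dish {dish.dish_id!r}: fvnl denominator (food weight excluding "
            "water) must be > 0"
        )
    return FvnlInfo(
        fvnl_weight_g=dish.ingredient_weight(FVNL_GROUPS),
        denominator_g=dish.food_weight_excl_water_g,
    )


def v_points(fvnl: FvnlInfo, config: ModelConfig) -> int:
    """V points (0-8) from the fvnl fraction; hard zero below 40%."""
    if fvnl.fraction < config.fvnl_zero_below_fraction:
        return 0
    return band_points(config.band_table("v"), fvnl.fraction)


def restricted_points(nutrients: NutrientVector,
                      config: ModelConfig) -> Tuple[int, int, int, int]:
    """(energy, satfat, sugars, sodium) points for one dish.

    The saturated-fat and sugars tables are materialised at the dish's own
    energy; with zero dish energy their anchors degenerate and the lookup
    falls back to widths at the reference energy intake.
    """
    energy = nutrients.energy_kcal
    return (
        band_points(config.band_table("energy"), energy),
        band_points(config.band_table("satfat", energy_kcal=energy), nutrients.satfat_g),
        band_points(config.band_table("sugars", energy_kcal=energy), nutrients.sugars_g),
        band_points(config.band_table("sodium"), nutrients.sodium_mg),
    )


def apply_protein_cap(baseline: int, v_pts: int, protein_pts_raw: int,
                      config: ModelConfig) -> int:
    """Zero the protein score when baseline >= 13 unless V points >= 5."""
    for name, value in (("baseline", baseline), ("v_pts", v_pts),
                        ("protein_pts_raw", protein_pts_raw)):
        if not isinstance(value, int) or value < 0:
            raise ValidationError(f"{name} must be a non-negative integer, got {value!r}")
    if baseline >= config.cap_baseline_threshold and v_pts < config.cap_v_exemption:
        return 0
    return protein_pts_raw


def score_dish(
    dish: Optional[DishRecord],
    config: ModelConfig,
    fvnl: Optional[FvnlInfo] = None,
    precomputed: Optional[ComponentPoints] = None,
) -> ScoreResult:
    """Score one dish.

    Either ``precomputed`` component points are supplied (fixture mode:
    the cap is re-applied from the raw protein score and the aggregates
    recomputed), or the dish's nutrient vector is banded from scratch, in
    which case an fvnl fraction must be available — passed explicitly or
    derivable from the ingredient list.
    """
    if precomputed is not None:
        restricted = (precomputed.energy_pts, precomputed.satfat_pts,
                      precomputed.sugars_pts, precomputed.sodium_pts)
        v = precomputed.v_pts
        protein_raw = precomputed.protein_pts_raw
        fiber = precomputed.fiber_pts
    elif dish is not None:
        restricted = restricted_points(dish.nutrients, config)
        if fvnl is None:
            fvnl = compute_fvnl(dish)
        v = v_points(fvnl, config)
        protein_raw = band_points(config.band_table("protein"), dish.nutrients.protein_g)
        fiber = band_points(config.band_table("fiber"), dish.nutrients.fiber_g)
    else:
        raise ValidationError(
            "score_dish needs either a dish with nutrients or precomputed "
            "component points"
        )
    baseline = sum(restricted)
    protein = apply_protein_cap(baseline, v, protein_raw, config)
    points = ComponentPoints(
        energy_pts=restricted[0], satfat_pts=restricted[1],
        sugars_pts=restricted[2], sodium_pts=restricted[3],
        v_pts=v, protein_pts_raw=protein_raw, protein_pts=protein,
        fiber_pts=fiber,
    )
    return ScoreResult.from_points(points)


def per_serving_score(result: ScoreResult, servings: float) -> float:
    """Optional post-processing: final score normalised per serving (SV).

    The published worked examples are all per dish as served; this helper
    exists for sensitivity analyses only.
    """
    if servings <= 0:
        raise ValidationError(f"servings must be > 0, got {servings!r}")
    return result.final_score / servings
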