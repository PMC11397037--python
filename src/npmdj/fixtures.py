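"""Worked-example fixtures and synthetic dish generation.

Two machine-readable tables ship with the package:

* the noodle-soup consumption scenarios (six noodle dishes, each scored
  with the soup left, half consumed, and fully consumed), and
* the 105-dish reference catalog (20 staples, 34 sides, 21 mains, 12
  mixed dishes, 18 mixed dishes with staple) with component points,
  weights, final scores and star ratings.

Both store the published values verbatim — including one catalog row
whose printed food weight looks like a typo (flagged, never silently
corrected) — with any typographic minus signs normalised to ASCII on
load.  Every row is validated against the score-arithmetic identities at
load time, which doubles as a transcription-integrity check.

The synthetic generator emits dishes whose ingredient lists satisfy one
category's defining rule *by construction*, with nutrient amounts drawn
from per-category ranges calibrated so that a catalog mixed in the
reference proportions lands near the published component-point medians.
It emulates point-level structure only: real recipes, cooking-loss
adjustments and nutrient covariance are out of its scope.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .types import (
    ComponentPoints,
    DishCategory,
    DishRecord,
    IngredientEntry,
    NutrientVector,
    ScoreResult,
    StarRating,
    ValidationError,
)

_TABLE_RESOURCES = {"T3": "table3.csv", "T4": "table4.csv"}

#: Expected catalog composition: dishes per category.
CATALOG_CATEGORY_COUNTS = {
    DishCategory.STAPLE: 20,
    DishCategory.SIDE: 34,
    DishCategory.MAIN: 21,
    DishCategory.MIXED: 12,
    DishCategory.MIXED_WITH_STAPLE: 18,
}


@dataclass(frozen=True)
class FixtureRow:
    """One transcribed worked-example row."""

    table: str
    dish_id: str
    name: str
    category: DishCategory
    scenario: Optional[str]
    food_weight_excl_water_g: float
    total_food_weight_g: float
    points: ComponentPoints
    baseline: int
    final_score: int
    rating_glyph: Optional[str] = None
    flagged: Optional[str] = None

    def __post_init__(self) -> None:
        # Transcription integrity: the printed aggregates must satisfy the
        # score identities exactly.
        result = ScoreResult.from_points(self.points)
        if result.baseline != self.baseline or result.final_score != self.final_score:
            raise ValidationError(
                f"fixture row {self.dish_id!r}: printed baseline/final "
                f"({self.baseline}/{self.final_score}) do not match the "
                f"component points ({result.baseline}/{result.final_score})"
            )

    @property
    def stars(self) -> Optional[StarRating]:
        if self.rating_glyph is None:
            return None
        return StarRating.from_glyphs(self.rating_glyph)

    def to_dish_record(self) -> DishRecord:
        """A nutrient-less dish record carrying this row's identity and
        weights, with the printed category as override (the catalog prints
        points, not recipes)."""
        return DishRecord(
            dish_id=self.dish_id,
            name=self.name,
            nutrients=NutrientVector(0, 0, 0, 0, 0, 0),
            food_weight_excl_water_g=self.food_weight_excl_water_g,
            total_food_weight_g=self.total_food_weight_g,
            category_override=self.category,
        )


def _normalise_minus(text: str) -> str:
    return text.replace("−", "-").replace("–", "-")


def load_fixtures(table: str) -> List[FixtureRow]:
    """Load the packaged fixture rows for table ``"T3"`` or ``"T4"``."""
    try:
        resource = _TABLE_RESOURCES[table]
    except KeyError:
        raise ValidationError(f"unknown fixture table {table!r}; expected T3 or T4")
    text = resources.files("npmdj.data").joinpath(resource).read_text("utf-8")
    rows: List[FixtureRow] = []
    for record in csv.DictReader(_normalise_minus(text).splitlines()):
        protein = int(record["protein_pts"])
        points = ComponentPoints(
            energy_pts=int(record["energy_pts"]),
            satfat_pts=int(record["satfat_pts"]),
            sugars_pts=int(record["sugars_pts"]),
            sodium_pts=int(record["sodium_pts"]),
            v_pts=int(record["v_pts"]),
            protein_pts_raw=protein,
            protein_pts=protein,
            fiber_pts=int(record["fiber_pts"]),
        )
        if table == "T3":
            dish_id = f"{record['dish_id']}:{record['scenario']}"
            scenario = record["scenario"]
            rating = None
        else:
            dish_id = f"t4-{int(record['no']):03d}"
            scenario = None
            rating = record["rating"] or None
        rows.append(FixtureRow(
            table=table,
            dish_id=dish_id,
            name=record["name"],
            category=DishCategory(record["category"]),
            scenario=scenario,
            food_weight_excl_water_g=float(record["food_weight_excl_water_g"]),
            total_food_weight_g=float(record["total_food_weight_g"]),
            points=points,
            baseline=int(record["baseline"]),
            final_score=int(record["final_score"]),
            rating_glyph=rating,
            flagged=(record.get("flagged") or None) if table == "T4" else None,
        ))
    return rows


# --------------------------------------------------------------------------
# Soup scenarios
# --------------------------------------------------------------------------

def soup_scenario(base: DishRecord, soup_nutrients: NutrientVector,
                  soup_food_weight_g: float, soup_total_weight_g: float,
                  fraction: float) -> DishRecord:
    """A noodle dish with ``fraction`` of its soup consumed.

    Linear mixing: nutrients and weights are the base (soup left in the
    bowl) plus ``fraction`` times the full soup contribution.  Published
    scenario rows deviate from exact linearity by a gram or two because
    their nutrient software rounds independently per scenario; dipped
    noodles (cold soba) are genuinely non-linear.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError(f"soup fraction must be within [0, 1], got {fraction!r}")
    nutrients = NutrientVector(
        energy_kcal=base.nutrients.energy_kcal + fraction * soup_nutrients.energy_kcal,
        satfat_g=base.nutrients.satfat_g + fraction * soup_nutrients.satfat_g,
        sugars_g=base.nutrients.sugars_g + fraction * soup_nutrients.sugars_g,
        sodium_mg=base.nutrients.sodium_mg + fraction * soup_nutrients.sodium_mg,
        protein_g=base.nutrients.protein_g + fraction * soup_nutrients.protein_g,
        fiber_g=base.nutrients.fiber_g + fraction * soup_nutrients.fiber_g,
    )
    return DishRecord(
        dish_id=f"{base.dish_id}+soup{fraction:.2f}",
        name=base.name,
        nutrients=nutrients,
        food_weight_excl_water_g=base.food_weight_excl_water_g + fraction * soup_food_weight_g,
        total_food_weight_g=base.total_food_weight_g + fraction * soup_total_weight_g,
        ingredients=(),
        category_override=base.category_override,
    )


# --------------------------------------------------------------------------
# Synthetic dishes
# --------------------------------------------------------------------------

ARCHETYPES = ("staple", "side", "main", "mixed", "mixed_with_staple")

#: Uniform sampling ranges for per-dish nutrient amounts, by archetype.
#: Units: kcal, g, g, mg, g, g.  Chosen to emulate standard Japanese
#: recipes per category: rice/bread/noodle staples; small vegetable-,
#: seaweed- and mushroom-based sides; meat/fish/egg/soy mains; stews and
#: one-plate staple combinations with seasoning-driven sodium.
ARCHETYPE_NUTRIENT_RANGES: Mapping[str, Mapping[str, Tuple[float, float]]] = {
    "staple": {
        "energy_kcal": (120, 380), "satfat_g": (0, 2), "sugars_g": (0, 3),
        "sodium_mg": (0, 900), "protein_g": (3, 9), "fiber_g": (1, 4),
    },
    "side": {
        "energy_kcal": (20, 120), "satfat_g": (0, 1.5), "sugars_g": (0.5, 6),
        "sodium_mg": (100, 800), "protein_g": (0.5, 4), "fiber_g": (1, 4),
    },
    "main": {
        "energy_kcal": (80, 300), "satfat_g": (0.5, 6), "sugars_g": (0, 2),
        "sodium_mg": (100, 700), "protein_g": (8, 25), "fiber_g": (0, 1),
    },
    "mixed": {
        "energy_kcal": (180, 550), "satfat_g": (2, 12), "sugars_g": (3, 15),
        "sodium_mg": (500, 1500), "protein_g": (10, 25), "fiber_g": (1, 4),
    },
    "mixed_with_staple": {
        "energy_kcal": (450, 800), "satfat_g": (2, 12), "sugars_g": (2, 12),
        "sodium_mg": (700, 2000), "protein_g": (15, 30), "fiber_g": (2, 5.5),
    },
}

#: Cooked carbohydrate content assumed for synthetic grain ingredients
#: (g carbohydrate per g cooked grain) and protein content for synthetic
#: protein-source ingredients (g protein per g cooked meat/fish/egg/soy).
GRAIN_CARB_FRACTION = 0.36
MEAT_PROTEIN_FRACTION = 0.20


@dataclass(frozen=True)
class SyntheticDishSpec:
    """A request for ``n`` reproducible dishes of one archetype."""

    archetype: str
    n: int
    seed: int
    nutrient_ranges: Optional[Mapping[str, Tuple[float, float]]] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError(f"n must be >= 1, got {self.n}")


def _sample_nutrients(rng: np.random.Generator,
                      ranges: Mapping[str, Tuple[float, float]]) -> NutrientVector:
    return NutrientVector(**{
        name: float(rng.uniform(lo, hi)) for name, (lo, hi) in ranges.items()
    })


def _build_ingredients(rng: np.random.Generator, archetype: str,
                       weight_g: float) -> Tuple[Tuple[IngredientEntry, ...], float]:
    """Ingredient list satisfying the archetype's defining rule, plus any
    water weight (added to the total weight only)."""
    ings: List[IngredientEntry] = []
    water = 0.0
    if archetype == "staple":
        frac = rng.uniform(0.75, 0.95)
        grain = frac * weight_g
        ings = [
            IngredientEntry("cooked grain", grain, "grain",
                            carbohydrate_g=GRAIN_CARB_FRACTION * grain,
                            is_main_ingredient=True),
            IngredientEntry("seasoning", weight_g - grain, "seasoning"),
        ]
    elif archetype == "side":
        frac = rng.uniform(0.75, 0.95)
        veg = frac * weight_g
        ings = [
            IngredientEntry("cooked vegetables", veg, "vegetable",
                            is_main_ingredient=True),
            IngredientEntry("seasoning", weight_g - veg, "seasoning"),
        ]
    elif archetype == "main":
        frac = rng.uniform(0.75, 0.95)
        meat = frac * weight_g
        ings = [
            IngredientEntry("cooked protein source", meat, "meat",
                            protein_g=MEAT_PROTEIN_FRACTION * meat,
                            is_main_ingredient=True),
            IngredientEntry("seasoning", weight_g - meat, "seasoning"),
        ]
    elif archetype == "mixed":
        meat_frac = rng.uniform(0.25, 0.40)
        veg_frac = rng.uniform(0.30, 0.45)
        meat = meat_frac * weight_g
        veg = veg_frac * weight_g
        rest = weight_g - meat - veg
        water = float(rng.uniform(0, 150))
        ings = [
            IngredientEntry("cooked protein source", meat, "meat",
                            protein_g=MEAT_PROTEIN_FRACTION * meat,
                            is_main_ingredient=True),
            IngredientEntry("cooked vegetables", veg, "vegetable",
                            is_main_ingredient=True),
            IngredientEntry("seasoning and other", rest, "seasoning"),
            IngredientEntry("stock", water, "water_stock"),
        ]
    elif archetype == "mixed_with_staple":
        grain_frac = rng.uniform(0.40, 0.60)
        meat_frac = rng.uniform(0.15, 0.25)
        veg_frac = rng.uniform(0.08, 0.18)
        grain = grain_frac * weight_g
        meat = meat_frac * weight_g
        veg = veg_frac * weight_g
        rest = weight_g - grain - meat - veg
        ings = [
            IngredientEntry("cooked grain", grain, "grain",
                            carbohydrate_g=GRAIN_CARB_FRACTION * grain,
                            is_main_ingredient=True),
            IngredientEntry("cooked protein source", meat, "meat",
                            protein_g=MEAT_PROTEIN_FRACTION * meat,
                            is_main_ingredient=True),
            IngredientEntry("cooked vegetables", veg, "vegetable",
                            is_main_ingredient=True),
            IngredientEntry("seasoning and other", rest, "seasoning"),
        ]
    else:
        raise ValidationError(
            f"unknown archetype {archetype!r}; expected one of {ARCHETYPES}"
        )
    return tuple(ings), water


_ARCHETYPE_WEIGHT_RANGES = {
    "staple": (100, 400),
    "side": (50, 200),
    "main": (40, 160),
    "mixed": (150, 400),
    "mixed_with_staple": (250, 450),
}

_ARCHETYPE_CATEGORY = {
    "staple": DishCategory.STAPLE,
    "side": DishCategory.SIDE,
    "main": DishCategory.MAIN,
    "mixed": DishCategory.MIXED,
    "mixed_with_staple": DishCategory.MIXED_WITH_STAPLE,
}


def generate_synthetic_dishes(spec: SyntheticDishSpec) -> List[DishRecord]:
    """Generate ``spec.n`` dishes of one archetype, reproducibly.

    Each dish's ingredient list satisfies its archetype's defining
    categorization rule by construction, and the dish_id embeds the
    intended archetype for round-trip testing.  No ``category_override``
    is set: classification must rediscover the archetype from the
    ingredients.
    """
    if spec.archetype not in ARCHETYPES:
        raise ValidationError(
            f"unknown archetype {spec.archetype!r}; expected one of {ARCHETYPES}"
        )
    rng = np.random.default_rng(spec.seed)
    ranges = spec.nutrient_ranges or ARCHETYPE_NUTRIENT_RANGES[spec.archetype]
    lo, hi = _ARCHETYPE_WEIGHT_RANGES[spec.archetype]
    dishes = []
    for i in range(spec.n):
        weight = float(rng.uniform(lo, hi))
        ingredients, water = _build_ingredients(rng, spec.archetype, weight)
        dishes.append(DishRecord(
            dish_id=f"{spec.archetype}-{spec.seed}-{i:04d}",
            name=f"synthetic {spec.archetype.replace('_', ' ')} dish {i}",
            nutrients=_sample_nutrients(rng, ranges),
            food_weight_excl_water_g=weight,
            total_food_weight_g=weight + water,
            ingredients=ingredients,
        ))
    return dishes


def intended_category(dish_id: str) -> DishCategory:
    """The archetype label embedded in a synthetic dish id."""
    archetype = dish_id.rsplit("-", 2)[0]
    return _ARCHETYPE_CATEGORY[archetype]


def generate_synthetic_catalog(
    seed: int,
    counts: Optional[Mapping[str, int]] = None,
) -> List[DishRecord]:
    """A synthetic catalog mixed in the reference category proportions
    (20/34/21/12/18 by default)."""
    if counts is None:
        counts = {cat.value if isinstance(cat, DishCategory) else cat: n
                  for cat, n in CATALOG_CATEGORY_COUNTS.items()}
    dishes = []
    for k, (archetype, n) in enumerate(counts.items()):
        sub_seed = np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2 ** 31)
        dishes.extend(generate_synthetic_dishes(
            SyntheticDishSpec(archetype=archetype, n=n, seed=int(sub_seed))
        ))
    return dishes
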