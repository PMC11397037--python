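"""Domain types for the Nutrient Profile Model for Dishes in Japan (NPM-DJ 1.0).

The model evaluates one dish in its as-consumed state.  Restricted
components (energy, saturated fat, total sugars, sodium) earn *baseline
points* through banded lookup tables; recommended components (fvnl weight
fraction, protein, dietary fiber) earn *modification points* that are
subtracted from the baseline.  Lower final scores are more favourable.

All quantities are per dish as served: kcal, g, or mg.  There is no
per-100 g or kJ mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Tuple


class ValidationError(ValueError):
    """An input violates a model invariant (negative nutrient, bad band table, ...)."""


class SchemaError(ValueError):
    """A dish/score table is missing required columns or keys."""


# --------------------------------------------------------------------------
# Dish categories and ingredient food groups
# --------------------------------------------------------------------------

class DishCategory(str, Enum):
    """The five NPM-DJ dish categories, plus a sentinel for dishes matching no rule."""

    STAPLE = "staple"
    SIDE = "side"
    MAIN = "main"
    MIXED = "mixed"
    MIXED_WITH_STAPLE = "mixed_with_staple"
    UNCLASSIFIED = "unclassified"


#: Food-group tags an ingredient may carry.
INGREDIENT_GROUPS = frozenset({
    "grain", "vegetable", "fruit", "potato", "legume_non_soy",
    "soybean_product", "mushroom", "seaweed", "nut_seed",
    "meat", "fish", "egg", "dairy",
    "seasoning", "oil_fat", "water_stock", "other",
})

#: Groups that make a dish a staple (grains: rice, bread, noodles).
GRAIN_GROUPS = frozenset({"grain"})

#: Groups that make a dish a side under the two-thirds weight rule.
#: Potatoes count here but are excluded from the fvnl (V-point) numerator.
SIDE_GROUPS = frozenset({
    "vegetable", "fruit", "potato", "legume_non_soy",
    "mushroom", "seaweed", "nut_seed",
})

#: Protein-source groups that make a dish a main.
PROTEIN_GROUPS = frozenset({"meat", "fish", "egg", "soybean_product"})

#: Numerator groups for the fvnl fraction (fruits, vegetables, nuts,
#: legumes, seaweed, seeds, mushrooms; potatoes deliberately absent).
FVNL_GROUPS = frozenset({
    "vegetable", "fruit", "legume_non_soy", "mushroom", "seaweed", "nut_seed",
})

#: Groups excluded from the cooked food weight (water and stock).
WATER_GROUPS = frozenset({"water_stock"})

#: mg sodium per g salt implied by the 7 g salt == 2756 mg sodium anchor.
SODIUM_MG_PER_G_SALT = 2756.0 / 7.0


def salt_to_sodium_mg(salt_g: float) -> float:
    """Convert grams of salt to mg sodium using the 2756 mg / 7 g anchor."""
    return salt_g * SODIUM_MG_PER_G_SALT


def sodium_mg_to_salt_g(sodium_mg: float) -> float:
    """Convert mg sodium to grams of salt-equivalent."""
    return sodium_mg / SODIUM_MG_PER_G_SALT


def _require_finite_nonneg(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise ValidationError(f"{name} must be finite and >= 0, got {value!r}")


# --------------------------------------------------------------------------
# Nutrients and ingredients
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NutrientVector:
    """Nutrient amounts per dish as served.

    ``sugars_g`` is total sugars (the sum of glucose, fructose, galactose,
    sucrose, maltose, lactose and trehalose), computed upstream from a
    carbohydrate composition table; it is an input here, never recomputed.
    """

    energy_kcal: float
    satfat_g: float
    sugars_g: float
    sodium_mg: float
    protein_g: float
    fiber_g: float

    def __post_init__(self) -> None:
        for name in ("energy_kcal", "satfat_g", "sugars_g",
                     "sodium_mg", "protein_g", "fiber_g"):
            _require_finite_nonneg(name, getattr(self, name))


@dataclass(frozen=True)
class IngredientEntry:
    """One cooked ingredient of a dish, tagged with its food group.

    ``is_main_ingredient`` marks the ingredients whose carbohydrate, weight,
    or protein drive the serving (SV) counts; which ingredient is "main" is
    a recipe-level judgement supplied by the caller, not inferred here.
    """

    name: str
    cooked_weight_g: float
    group: str
    carbohydrate_g: float = 0.0
    protein_g: float = 0.0
    is_main_ingredient: bool = False

    def __post_init__(self) -> None:
        if self.group not in INGREDIENT_GROUPS:
            raise ValidationError(
                f"unknown food group {self.group!r} for ingredient {self.name!r}; "
                f"expected one of {sorted(INGREDIENT_GROUPS)}"
            )
        _require_finite_nonneg("cooked_weight_g", self.cooked_weight_g)
        _require_finite_nonneg("carbohydrate_g", self.carbohydrate_g)
        _require_finite_nonneg("protein_g", self.protein_g)
        if self.carbohydrate_g > self.cooked_weight_g:
            raise ValidationError(
                f"ingredient {self.name!r}: carbohydrate_g ({self.carbohydrate_g}) "
                f"exceeds cooked_weight_g ({self.cooked_weight_g})"
            )
        if self.protein_g > self.cooked_weight_g:
            raise ValidationError(
                f"ingredient {self.name!r}: protein_g ({self.protein_g}) "
                f"exceeds cooked_weight_g ({self.cooked_weight_g})"
            )


#: Absolute tolerance (g) for reconciling the ingredient weight sum with
#: the declared cooked food weight excluding water.
WEIGHT_RECONCILIATION_TOL_G = 2.0


@dataclass(frozen=True)
class DishRecord:
    """One dish at the as-consumed state.

    The ingredient list may be empty when only nutrient-level scoring is
    wanted (the worked catalog rows carry points, not recipes); dish
    classification and the fvnl fraction then require ``category_override``
    or an explicit fvnl input.
    """

    dish_id: str
    name: str
    nutrients: NutrientVector
    food_weight_excl_water_g: float
    total_food_weight_g: float
    ingredients: Tuple[IngredientEntry, ...] = ()
    category_override: Optional[DishCategory] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "ingredients", tuple(self.ingredients))
        _require_finite_nonneg("food_weight_excl_water_g", self.food_weight_excl_water_g)
        _require_finite_nonneg("total_food_weight_g", self.total_food_weight_g)
        if self.food_weight_excl_water_g > self.total_food_weight_g:
            raise ValidationError(
                f"dish {self.dish_id!r}: food_weight_excl_water_g "
                f"({self.food_weight_excl_water_g}) exceeds total_food_weight_g "
                f"({self.total_food_weight_g})"
            )
        if self.ingredients:
            non_water = sum(
                ing.cooked_weight_g for ing in self.ingredients
                if ing.group not in WATER_GROUPS
            )
            tol = max(WEIGHT_RECONCILIATION_TOL_G, 0.02 * self.food_weight_excl_water_g)
            if abs(non_water - self.food_weight_excl_water_g) > tol:
                raise ValidationError(
                    f"dish {self.dish_id!r}: non-water ingredient weights sum to "
                    f"{non_water:.1f} g but food_weight_excl_water_g is "
                    f"{self.food_weight_excl_water_g:.1f} g (tolerance {tol:.1f} g)"
                )

    def ingredient_weight(self, groups: Iterable[str],
                          main_only: bool = False) -> float:
        """Total cooked weight (g) of ingredients whose group is in ``groups``."""
        groups = frozenset(groups)
        return sum(
            ing.cooked_weight_g for ing in self.ingredients
            if ing.group in groups and (ing.is_main_ingredient or not main_only)
        )


# --------------------------------------------------------------------------
# Serving counts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ServingCounts:
    """Serving (SV) tallies in the Japanese Food Guide sense.

    One staple SV is 40 g carbohydrate from the main grain ingredient, one
    side SV is 70 g of the main side-group ingredient, and one main SV is
    6 g protein from the main protein-source ingredient.
    """

    staple_sv: float
    side_sv: float
    main_sv: float

    def __post_init__(self) -> None:
        for name in ("staple_sv", "side_sv", "main_sv"):
            _require_finite_nonneg(name, getattr(self, name))


# --------------------------------------------------------------------------
# Component points and score results
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ComponentPoints:
    """The seven component point scores of one dish.

    ``protein_pts_raw`` is the banded protein score before the protein cap;
    ``protein_pts`` is the score that enters the modification sum (either
    the raw value or zero).
    """

    energy_pts: int
    satfat_pts: int
    sugars_pts: int
    sodium_pts: int
    v_pts: int
    protein_pts_raw: int
    protein_pts: int
    fiber_pts: int

    def __post_init__(self) -> None:
        for name in ("energy_pts", "satfat_pts", "sugars_pts", "sodium_pts",
                     "v_pts", "protein_pts_raw", "protein_pts", "fiber_pts"):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {value!r}")
        if self.v_pts > 8:
            raise ValidationError(f"v_pts must be <= 8, got {self.v_pts}")
        if self.protein_pts not in (0, self.protein_pts_raw):
            raise ValidationError(
                f"protein_pts ({self.protein_pts}) must be 0 or equal to "
                f"protein_pts_raw ({self.protein_pts_raw})"
            )

    @property
    def baseline(self) -> int:
        return self.energy_pts + self.satfat_pts + self.sugars_pts + self.sodium_pts

    @property
    def modification(self) -> int:
        return self.v_pts + self.protein_pts + self.fiber_pts


@dataclass(frozen=True)
class ScoreResult:
    """Aggregated NPM-DJ score of one dish.

    ``modification`` is reported as a non-negative magnitude; the sign
    convention is that it is *subtracted* from the baseline, so
    ``final_score = baseline - modification``.  ``cap_applied`` is set only
    when the protein cap zeroed a nonzero raw protein score.
    """

    points: ComponentPoints
    baseline: int
    modification: int
    final_score: int
    cap_applied: bool = False

    def __post_init__(self) -> None:
        if self.baseline != self.points.baseline:
            raise ValidationError(
                f"baseline {self.baseline} != sum of restricted points {self.points.baseline}"
            )
        if self.modification != self.points.modification:
            raise ValidationError(
                f"modification {self.modification} != sum of V/protein/fiber points "
                f"{self.points.modification}"
            )
        if self.final_score != self.baseline - self.modification:
            raise ValidationError(
                f"final_score {self.final_score} != baseline - modification "
                f"({self.baseline} - {self.modification})"
            )

    @classmethod
    def from_points(cls, points: ComponentPoints) -> "ScoreResult":
        """Build a result whose aggregates follow from the component points."""
        return cls(
            points=points,
            baseline=points.baseline,
            modification=points.modification,
            final_score=points.baseline - points.modification,
            cap_applied=points.protein_pts == 0 and points.protein_pts_raw > 0,
        )


# --------------------------------------------------------------------------
# fvnl
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FvnlInfo:
    """Weight fraction of fvnl groups in the cooked food excluding water/stock."""

    fvnl_weight_g: float
    denominator_g: float

    def __post_init__(self) -> None:
        _require_finite_nonneg("fvnl_weight_g", self.fvnl_weight_g)
        if not math.isfinite(self.denominator_g) or self.denominator_g <= 0:
            raise ValidationError(
                f"denominator_g must be finite and > 0, got {self.denominator_g!r}"
            )
        if self.fvnl_weight_g > self.denominator_g * (1 + 1e-9):
            raise ValidationError(
                f"fvnl weight ({self.fvnl_weight_g}) exceeds the cooked food weight "
                f"({self.denominator_g})"
            )

    @property
    def fraction(self) -> float:
        return min(self.fvnl_weight_g / self.denominator_g, 1.0)

    @classmethod
    def from_fraction(cls, fraction: float) -> "FvnlInfo":
        """Build from an externally supplied fvnl fraction (denominator 1 g)."""
        return cls(fvnl_weight_g=float(fraction), denominator_g=1.0)


# --------------------------------------------------------------------------
# Band tables and model configuration
# --------------------------------------------------------------------------

COMPONENTS = ("energy", "satfat", "sugars", "sodium", "v", "protein", "fiber")


@dataclass(frozen=True)
class BandTable:
    """A banded point lookup: the k-th threshold is the lower bound of the
    k-point band, and a threshold must be *strictly* exceeded to earn its
    point.  Lookup is therefore monotone non-decreasing in the amount.
    """

    component: str
    unit: str
    thresholds: Tuple[float, ...]
    max_points: int
    provenance: str = "anchored"

    def __post_init__(self) -> None:
        object.__setattr__(self, "thresholds", tuple(float(t) for t in self.thresholds))
        if self.component not in COMPONENTS:
            raise ValidationError(f"unknown component {self.component!r}")
        if not self.thresholds:
            raise ValidationError(f"{self.component}: band table needs at least one threshold")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValidationError(
                f"{self.component}: band thresholds must be strictly increasing, "
                f"got {self.thresholds}"
            )
        if self.max_points < 1:
            raise ValidationError(f"{self.component}: max_points must be >= 1")


def linear_band_table(component: str, unit: str, width: float, max_points: int,
                      provenance: str = "anchored") -> BandTable:
    """Equal-width bands: thresholds at width, 2*width, ..., max_points*width."""
    if width <= 0:
        raise ValidationError(f"{component}: band width must be > 0, got {width}")
    return BandTable(
        component=component, unit=unit,
        thresholds=tuple(width * (k + 1) for k in range(max_points)),
        max_points=max_points, provenance=provenance,
    )


def span_band_table(component: str, unit: str, start: float, stop: float,
                    max_points: int, provenance: str = "reconstructed") -> BandTable:
    """``max_points`` thresholds evenly spaced from ``start`` to ``stop``
    inclusive: the final point opens only strictly beyond ``stop``."""
    if stop <= start:
        raise ValidationError(f"{component}: span stop must exceed start")
    if max_points < 2:
        raise ValidationError(f"{component}: a span table needs max_points >= 2")
    step = (stop - start) / (max_points - 1)
    return BandTable(
        component=component, unit=unit,
        thresholds=tuple(start + step * k for k in range(max_points)),
        max_points=max_points, provenance=provenance,
    )


@dataclass(frozen=True)
class ModelConfig:
    """Declarative model constants and one band specification per component.

    Band specs are mappings with a ``mode`` key:

    ``linear``
        equal-width bands (``width``, ``max_points``);
    ``span``
        equal bands across a closed amount span (``start``, ``stop``);
    ``energy_linear``
        equal-width bands whose width is derived per dish from its energy
        (``energy_fraction`` of the dish energy, converted to grams by
        ``kcal_per_g``) — used for saturated fat (7%E) and sugars (10%E);
    ``thresholds``
        explicit threshold list.
    """

    model_version: str = "NPM-DJ-1.0"
    energy_reference_kcal: float = 2200.0
    sodium_reference_mg: float = 2756.0
    salt_target_g: float = 7.0
    protein_nrv_g: float = 81.0
    fiber_nrv_g: float = 19.0
    band_start_fraction: float = 0.0375
    satfat_energy_fraction: float = 0.07
    sugars_energy_fraction: float = 0.10
    satfat_kcal_per_g: float = 9.0
    sugars_kcal_per_g: float = 4.0
    fvnl_zero_below_fraction: float = 0.40
    cap_baseline_threshold: int = 13
    cap_v_exemption: int = 5
    bands: Mapping[str, Mapping[str, object]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("energy_reference_kcal", "sodium_reference_mg", "salt_target_g",
                     "protein_nrv_g", "fiber_nrv_g"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        for name in ("cap_baseline_threshold", "cap_v_exemption"):
            value = getattr(self, name)
            if not isinstance(value, int) or value <= 0:
                raise ValidationError(f"{name} must be a positive integer, got {value!r}")
        # Fail fast on malformed band specs: build every energy-independent
        # table once, and the energy-relative ones at the reference energy.
        for component in COMPONENTS:
            if component in self.bands:
                self.band_table(component, energy_kcal=self.energy_reference_kcal)

    def band_table(self, component: str,
                   energy_kcal: Optional[float] = None) -> BandTable:
        """Materialise the band table for ``component``.

        For energy-relative components (saturated fat, sugars) the
        effective gram thresholds depend on the dish energy; pass the dish
        ``energy_kcal``.  A dish energy of zero makes the energy-relative
        anchors degenerate, so lookup falls back to the widths computed at
        the reference energy intake.
        """
        try:
            spec = self.bands[component]
        except KeyError:
            raise ValidationError(f"no band specification for component {component!r}")
        mode = spec.get("mode", "linear")
        unit = str(spec.get("unit", ""))
        max_points = int(spec["max_points"])
        provenance = str(spec.get("provenance", "anchored"))
        if mode == "linear":
            return linear_band_table(component, unit, float(spec["width"]),
                                     max_points, provenance)
        if mode == "span":
            return span_band_table(component, unit, float(spec["start"]),
                                   float(spec["stop"]), max_points, provenance)
        if mode == "energy_linear":
            energy = energy_kcal if energy_kcal and energy_kcal > 0 else self.energy_reference_kcal
            width = float(spec["energy_fraction"]) * energy / float(spec["kcal_per_g"])
            return linear_band_table(component, unit, width, max_points, provenance)
        if mode == "thresholds":
            return BandTable(component=component, unit=unit,
                             thresholds=tuple(spec["thresholds"]),
                             max_points=max_points, provenance=provenance)
        raise ValidationError(f"{component}: unknown band mode {mode!r}")


# --------------------------------------------------------------------------
# Ratings
# --------------------------------------------------------------------------

#: The ten permitted star values, best (5.0) to worst (0.5).
STAR_VALUES = tuple(5.0 - 0.5 * k for k in range(10))


@dataclass(frozen=True)
class StarRating:
    """A within-category star rating, 0.5 to 5.0 in half-star steps."""

    stars: float

    def __post_init__(self) -> None:
        if self.stars not in STAR_VALUES:
            raise ValidationError(f"stars must be one of {STAR_VALUES}, got {self.stars!r}")

    @property
    def glyphs(self) -> str:
        """Glyph form: each full star is one black star, a trailing half
        star is one white star (so 3.5 stars renders with three black stars
        and one white)."""
        full = int(self.stars)
        half = self.stars - full >= 0.5
        return "★" * full + ("☆" if half else "")

    @classmethod
    def from_glyphs(cls, glyphs: str) -> "StarRating":
        full = glyphs.count("★")
        half = glyphs.count("☆")
        if half > 1 or not set(glyphs) <= {"★", "☆"} or full + half == 0:
            raise ValidationError(f"unparseable star glyphs {glyphs!r}")
        return cls(stars=full + 0.5 * half)


@dataclass(frozen=True)
class RatingCutpoints:
    """Decile cutpoints of one category's final-score distribution.

    ``cutpoints`` are the unrounded 10th..90th percentiles used for star
    assignment; ``display_thresholds`` are the half-up-rounded integers
    published in the category threshold table (display only).
    """

    category: DishCategory
    cutpoints: Tuple[float, ...]
    display_thresholds: Tuple[int, ...]
    n: int

    def __post_init__(self) -> None:
        if len(self.cutpoints) != 9 or len(self.display_thresholds) != 9:
            raise ValidationError("exactly nine decile cutpoints are required")
        if any(b < a for a, b in zip(self.cutpoints, self.cutpoints[1:])):
            raise ValidationError(f"cutpoints must be non-decreasing: {self.cutpoints}")
        if any(b < a for a, b in zip(self.display_thresholds, self.display_thresholds[1:])):
            raise ValidationError(
                f"display thresholds must be non-decreasing: {self.display_thresholds}"
            )
        if self.n < 1:
            raise ValidationError("n must be >= 1")
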