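"""Readers and writers for dish tables, score tables, and model configuration.

Dish tables are UTF-8 CSV (comma separator, ``.`` decimal, mandatory
header) or JSON.  In CSV form an optional second file keyed by ``dish_id``
carries the ingredient lists; in JSON form ingredients nest inside each
dish object.  The packaged default model configuration is returned by
:func:`load_model_config` when no path is given; a user configuration may
override any subset of keys (including a single component's band table)
and inherits the rest.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
import yaml

from .types import (
    DishCategory,
    DishRecord,
    IngredientEntry,
    ModelConfig,
    NutrientVector,
    SchemaError,
    ScoreResult,
    StarRating,
    ValidationError,
)

NUTRIENT_COLUMNS = (
    "energy_kcal", "satfat_g", "sugars_g", "sodium_mg", "protein_g", "fiber_g",
)
DISH_COLUMNS = (
    "dish_id", "name", *NUTRIENT_COLUMNS,
    "food_weight_excl_water_g", "total_food_weight_g",
)
INGREDIENT_COLUMNS = (
    "dish_id", "name", "cooked_weight_g", "group",
    "carbohydrate_g", "protein_g", "is_main_ingredient",
)

#: Column order of a written score table (the worked-catalog layout).
SCORE_COLUMNS = (
    "dish_id", "name", "category",
    "food_weight_excl_water_g", "total_food_weight_g",
    "energy_pts", "satfat_pts", "sugars_pts", "sodium_pts", "baseline",
    "v_pts", "protein_pts", "fiber_pts", "final_score",
    "cap_applied", "stars", "rating",
)


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {', '.join(missing)}")


def _parse_nutrients(row: Mapping[str, object], dish_id: str) -> NutrientVector:
    values = {}
    for col in NUTRIENT_COLUMNS:
        raw = row[col]
        try:
            value = float(raw)
        except (TypeError, ValueError):
            raise ValidationError(f"dish {dish_id!r}: {col} is not numeric: {raw!r}")
        values[col] = value
    try:
        return NutrientVector(**values)
    except ValidationError as exc:
        raise ValidationError(f"dish {dish_id!r}: {exc}") from exc


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    return str(value).strip().lower() in ("1", "true", "yes", "y")


def _ingredient_from_mapping(entry: Mapping[str, object], dish_id: str) -> IngredientEntry:
    try:
        return IngredientEntry(
            name=str(entry["name"]),
            cooked_weight_g=float(entry["cooked_weight_g"]),
            group=str(entry["group"]),
            carbohydrate_g=float(entry.get("carbohydrate_g", 0) or 0),
            protein_g=float(entry.get("protein_g", 0) or 0),
            is_main_ingredient=_parse_bool(entry.get("is_main_ingredient", False)),
        )
    except KeyError as exc:
        raise SchemaError(f"dish {dish_id!r}: ingredient entry missing key {exc}")
    except ValidationError as exc:
        raise ValidationError(f"dish {dish_id!r}: {exc}") from exc


def _dish_from_mapping(row: Mapping[str, object],
                       ingredients: Tuple[IngredientEntry, ...]) -> DishRecord:
    dish_id = str(row["dish_id"])
    override = row.get("category_override")
    if override is not None and not (isinstance(override, float) and pd.isna(override)):
        override = str(override).strip()
        override = DishCategory(override) if override else None
    else:
        override = None
    try:
        return DishRecord(
            dish_id=dish_id,
            name=str(row["name"]),
            nutrients=_parse_nutrients(row, dish_id),
            food_weight_excl_water_g=float(row["food_weight_excl_water_g"]),
            total_food_weight_g=float(row["total_food_weight_g"]),
            ingredients=ingredients,
            category_override=override,
        )
    except ValidationError as exc:
        raise ValidationError(f"dish {dish_id!r}: {exc}") from exc


def read_dish_table(path: str | Path, format: Optional[str] = None,
                    ingredients_path: Optional[str | Path] = None) -> List[DishRecord]:
    """Read dish records from a CSV or JSON table.

    ``format`` defaults to the file suffix.  With CSV input, an optional
    ``ingredients_path`` CSV (keyed by ``dish_id``) supplies the
    ingredient lists; JSON input nests ingredients directly.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "json":
        rows = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(rows, list):
            raise SchemaError("JSON dish table must be a list of dish objects")
        records = []
        for row in rows:
            missing = [k for k in DISH_COLUMNS if k not in row]
            if missing:
                raise SchemaError(
                    f"dish object is missing key(s): {', '.join(missing)}"
                )
            ings = tuple(_ingredient_from_mapping(e, str(row["dish_id"]))
                         for e in (row.get("ingredients") or []))
            records.append(_dish_from_mapping(row, ings))
        return records
    if fmt != "csv":
        raise ValueError(f"unsupported dish table format {fmt!r}")

    df = pd.read_csv(path)
    _require_columns(df, DISH_COLUMNS, f"dish table {path.name}")
    by_dish: dict[str, List[IngredientEntry]] = {}
    if ingredients_path is not None:
        ing_df = pd.read_csv(ingredients_path)
        _require_columns(ing_df, INGREDIENT_COLUMNS,
                         f"ingredient table {Path(ingredients_path).name}")
        for _, row in ing_df.iterrows():
            entry = _ingredient_from_mapping(row, str(row["dish_id"]))
            by_dish.setdefault(str(row["dish_id"]), []).append(entry)
    records = []
    for _, row in df.iterrows():
        dish_id = str(row["dish_id"])
        records.append(_dish_from_mapping(row, tuple(by_dish.get(dish_id, ()))))
    return records


def write_dish_table(dishes: Sequence[DishRecord], path: str | Path) -> None:
    """Write dish records as JSON (the lossless nested representation)."""
    payload = []
    for dish in dishes:
        payload.append({
            "dish_id": dish.dish_id,
            "name": dish.name,
            **{col: getattr(dish.nutrients, col) for col in NUTRIENT_COLUMNS},
            "food_weight_excl_water_g": dish.food_weight_excl_water_g,
            "total_food_weight_g": dish.total_food_weight_g,
            "category_override": dish.category_override.value if dish.category_override else None,
            "ingredients": [
                {
                    "name": ing.name,
                    "cooked_weight_g": ing.cooked_weight_g,
                    "group": ing.group,
                    "carbohydrate_g": ing.carbohydrate_g,
                    "protein_g": ing.protein_g,
                    "is_main_ingredient": ing.is_main_ingredient,
                }
                for ing in dish.ingredients
            ],
        })
    Path(path).write_text(json.dumps(payload, ensure_ascii=False, indent=1),
                          encoding="utf-8")


def write_score_table(
    results: Sequence[Tuple[DishRecord, ScoreResult, Optional[StarRating]]],
    path: str | Path,
    format: str = "csv",
    categories: Optional[Mapping[str, DishCategory]] = None,
) -> None:
    """Write scored dishes in the worked-catalog column layout.

    One row per dish: identity, weights, the seven component points,
    baseline, final score, and the star rating (numeric and glyph form).
    Re-reading with :func:`read_score_table` reproduces every value.
    """
    if not results:
        raise ValueError("cannot write an empty score table")
    rows = []
    for dish, score, rating in results:
        category = None
        if categories is not None:
            category = categories.get(dish.dish_id)
        if category is None:
            category = dish.category_override
        rows.append({
            "dish_id": dish.dish_id,
            "name": dish.name,
            "category": category.value if category else "",
            "food_weight_excl_water_g": dish.food_weight_excl_water_g,
            "total_food_weight_g": dish.total_food_weight_g,
            "energy_pts": score.points.energy_pts,
            "satfat_pts": score.points.satfat_pts,
            "sugars_pts": score.points.sugars_pts,
            "sodium_pts": score.points.sodium_pts,
            "baseline": score.baseline,
            "v_pts": score.points.v_pts,
            "protein_pts": score.points.protein_pts,
            "fiber_pts": score.points.fiber_pts,
            "final_score": score.final_score,
            "cap_applied": score.cap_applied,
            "stars": rating.stars if rating else "",
            "rating": rating.glyphs if rating else "",
        })
    df = pd.DataFrame(rows, columns=list(SCORE_COLUMNS))
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "json":
        path.write_text(df.to_json(orient="records", force_ascii=False),
                        encoding="utf-8")
    else:
        raise ValueError(f"unsupported score table format {format!r}")


def read_score_table(path: str | Path, format: str = "csv") -> pd.DataFrame:
    """Read back a score table written by :func:`write_score_table`."""
    path = Path(path)
    if format == "csv":
        df = pd.read_csv(path)
    elif format == "json":
        df = pd.read_json(path, orient="records")
    else:
        raise ValueError(f"unsupported score table format {format!r}")
    _require_columns(df, SCORE_COLUMNS, f"score table {path.name}")
    return df


# --------------------------------------------------------------------------
# Model configuration
# --------------------------------------------------------------------------

_CONFIG_RESOURCE = "default_config.json"


def _default_config_dict() -> dict:
    text = resources.files("npmdj.data").joinpath(_CONFIG_RESOURCE).read_text("utf-8")
    return json.loads(text)


def load_model_config(path: Optional[str | Path] = None) -> ModelConfig:
    """Load the model configuration.

    Without ``path`` the packaged NPM-DJ-1.0 defaults are returned.  A
    user file (JSON or YAML) overrides only the keys it sets: scalar
    constants replace the default, and each component entry under
    ``bands`` replaces that component's table while all others keep their
    defaults.
    """
    data = _default_config_dict()
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        user = yaml.safe_load(text)
        if not isinstance(user, dict):
            raise SchemaError("model config must be a mapping")
        bands = dict(data["bands"])
        bands.update(user.get("bands", {}))
        data.update({k: v for k, v in user.items() if k != "bands"})
        data["bands"] = bands
    known = {f for f in ModelConfig.__dataclass_fields__}
    kwargs = {k: v for k, v in data.items() if k in known}
    try:
        return ModelConfig(**kwargs)
    except ValidationError as exc:
        raise ValidationError(f"invalid model config: {exc}") from exc
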