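"""Within-category star ratings from decile cutpoints.

Final scores are ranked *within* each dish category: the category's score
distribution is cut at its nine deciles (10th..90th percentile, linear
interpolation at fractional index ``(n-1)*k/10`` — the common "type 7"
quantile), and a dish earns 5.0 stars down to 0.5 stars depending on the
first unrounded cutpoint its score does not exceed.  Lower scores earn
more stars.  The published per-category threshold table shows the
cutpoints rounded half-up for display; star assignment always uses the
unrounded values, which is what disambiguates scores sitting exactly on a
rounded threshold.

Ratings are relative to the catalog they were computed from: with fewer
than ten dishes in a category the deciles degenerate and neighbouring
ratings can share a threshold, so a warning is emitted.
"""

from __future__ import annotations

import math
import warnings
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .types import (
    DishCategory,
    DishRecord,
    RatingCutpoints,
    ScoreResult,
    StarRating,
    ValidationError,
)

#: Category sizes below this trigger a degenerate-decile warning.
SMALL_CATEGORY_N = 10

#: Supported quantile conventions (numpy interpolation methods).  The
#: default, linear interpolation, is the convention that reproduces the
#: published threshold table; the others are exposed for sensitivity
#: analysis only.
QUANTILE_METHODS = ("linear", "lower", "higher", "nearest", "midpoint")


def round_half_up(x: float) -> int:
    """Round half-up on the signed value: 5.5 -> 6, -0.2 -> 0, -1.2 -> -1."""
    return int(math.floor(x + 0.5))


def decile_cutpoints(scores: Sequence[int], category: DishCategory,
                     method: str = "linear") -> RatingCutpoints:
    """Nine decile cutpoints of a category's final-score distribution."""
    scores = list(scores)
    if not scores:
        raise ValidationError(f"category {category.value!r} has no scores")
    if method not in QUANTILE_METHODS:
        raise ValidationError(f"unknown quantile method {method!r}")
    cutpoints = tuple(
        float(q) for q in np.percentile(scores, np.arange(10, 100, 10), method=method)
    )
    if len(scores) < SMALL_CATEGORY_N:
        warnings.warn(
            f"category {category.value!r} has only {len(scores)} dishes; decile "
            "cutpoints are degenerate and ratings within it are unstable",
            stacklevel=2,
        )
    return RatingCutpoints(
        category=category,
        cutpoints=cutpoints,
        display_thresholds=tuple(round_half_up(q) for q in cutpoints),
        n=len(scores),
    )


def assign_stars(score: int, cutpoints: RatingCutpoints) -> StarRating:
    """Stars for a final score against a category's unrounded cutpoints.

    The j-th cutpoint (j = 1..9) is the last score still worth
    ``5 - 0.5*(j-1)`` stars; a score above all nine earns 0.5 stars.
    Monotone: a higher score never earns more stars.
    """
    for j, q in enumerate(cutpoints.cutpoints, start=1):
        if score <= q:
            return StarRating(stars=5.0 - 0.5 * (j - 1))
    return StarRating(stars=0.5)


def rate_catalog(
    results: Sequence[Tuple[DishRecord, ScoreResult]],
    categories: Union[Mapping[str, DishCategory], Sequence[DishCategory]],
    cutpoints: Optional[Mapping[DishCategory, RatingCutpoints]] = None,
    method: str = "linear",
) -> Tuple[List[Tuple[DishRecord, StarRating]], Dict[DishCategory, RatingCutpoints]]:
    """Rate every dish of a catalog within its category.

    ``categories`` maps ``dish_id`` to category (or is a sequence aligned
    with ``results``).  Cutpoints are computed per category from the
    catalog itself unless a frozen ``cutpoints`` mapping is supplied, in
    which case new dishes are rated deterministically against it without
    recomputing any distribution.
    """
    if not results:
        raise ValidationError("cannot rate an empty catalog")
    if isinstance(categories, Mapping):
        cats = []
        for dish, _ in results:
            try:
                cats.append(categories[dish.dish_id])
            except KeyError:
                raise ValidationError(f"dish {dish.dish_id!r} has no category")
    else:
        if len(categories) != len(results):
            raise ValidationError("categories sequence must align with results")
        cats = list(categories)

    if cutpoints is None:
        by_category: Dict[DishCategory, List[int]] = {}
        for (dish, score), category in zip(results, cats):
            by_category.setdefault(category, []).append(score.final_score)
        cutpoints = {
            category: decile_cutpoints(scores, category, method=method)
            for category, scores in by_category.items()
        }
    missing = {c for c in cats if c not in cutpoints}
    if missing:
        names = ", ".join(sorted(c.value for c in missing))
        raise ValidationError(f"no rating cutpoints for category: {names}")

    rated = [
        (dish, assign_stars(score.final_score, cutpoints[category]))
        for (dish, score), category in zip(results, cats)
    ]
    return rated, dict(cutpoints)


def threshold_table(cutpoints: Mapping[DishCategory, RatingCutpoints]) -> pd.DataFrame:
    """The per-category display threshold table.

    Rows are the ratings from five stars down to half a star; each cell is
    the highest (rounded) final score still earning that rating, with the
    half-star row open-ended.
    """
    ratings = [StarRating(5.0 - 0.5 * k) for k in range(10)]
    data = {}
    for category, cp in cutpoints.items():
        column = [*(str(t) for t in cp.display_thresholds), "-"]
        data[category.value] = column
    index = [r.glyphs for r in ratings]
    df = pd.DataFrame(data, index=index)
    df.index.name = "rating"
    return df
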