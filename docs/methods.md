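# Methods

This note records how `npmdj` implements NPM-DJ 1.0: the procedure, the
constants, the choices made where the published description leaves the
design open, and what the synthetic data does and does not emulate.

## Evaluation basis

Every score is computed per dish as served, in kcal / g / mg.  The model's
framing mentions per-serving (SV) evaluation, but all published worked
scores are per dish, so the per-dish basis is the primary mode here;
`per_serving_score` divides a final score by an SV count as an optional
post-processing step and plays no part in validation.  Inputs arrive as
per-dish nutrient amounts; total sugars is the upstream sum of the seven
mono- and disaccharides from a carbohydrate composition table and is never
recomputed.  Sodium is taken in mg; the salt↔sodium converter uses the
anchor 7 g salt ≡ 2756 mg sodium (393.71 mg/g), so the model's own salt
target maps exactly onto its sodium reference.

## Categorization

Step 1 compares food-group weight *fractions* of the cooked food weight
excluding water and stock against 2/3 with a strict `>` (the rule reads
"more than 2/3"); at most one family can qualify, since two shares above
2/3 would exceed the whole.  Step 2 compares SV tallies against 0.5 with
`>=` ("0.5 or more").  Both comparisons are taken verbatim from the
category table; they are constants of the classifier, not configuration.
Potatoes belong to the side family for the 2/3 rule yet are excluded from
the fvnl numerator — the two group sets are distinct frozen constants.
Fruit is treated as side-forming and fvnl-countable; the category table
does not list fruit explicitly, so this is a documented package choice.
Which ingredient is a dish's "main ingredient" is a recipe-level judgement
the caller supplies through `is_main_ingredient`; the classifier never
infers it from names.  Dishes matching neither step-2 rule come back
`UNCLASSIFIED` rather than being guessed.

## Band tables

A band table is a strictly increasing threshold sequence; an amount earns
one point per threshold it *strictly* exceeds, clipped to the component
maximum.  The strict boundary is applied uniformly: "the band starts at x"
means x itself still scores zero and the point opens just beyond it.  The
boundary semantics are data-driven (the table is config), so sensitivity
analyses can swap conventions without touching code.

Anchored tables (fixed by the published anchors, marked `anchored` in the
config):

| component | first threshold | width | max |
|---|---|---|---|
| energy | 3.75 % × 2200 kcal = 82.5 kcal | 82.5 kcal | 9 |
| sodium | 3.75 % × 2756 mg = 103.35 mg | 103.35 mg | 30 |

Equal widths follow the rule that bands from one point on repeat the width
of the zero-point band.  The maxima are the largest points observed in the
reference catalog and are configurable.

Reconstructed tables (`reconstructed` in the config): the published
description fixes only the anchors of the saturated-fat (7 %E), sugars
(10 %E), protein (3.75 % of the 81 g NRV = 3.0375 g) and fiber (3.75 % of
19 g = 0.7125 g) tables, plus qualitative notes (protein adjusted 2–15
points against the HSR scale; fiber "linear 1–5" in one sentence and "2–5"
in the next — that contradiction is preserved as a config comment, not
resolved).  The packaged defaults extend each anchor with equal widths.
Saturated fat and sugars are energy-relative: their gram widths are
derived per dish as `0.07·E/9` and `0.10·E/4` (9 and 4 kcal/g energy
densities).  With zero dish energy those anchors degenerate, so lookup
falls back to the widths at the 2200 kcal reference — a defined, documented
fallback rather than an error, since a zero-energy dish with nonzero
saturated fat is degenerate input to begin with.

The V table awards 0–8 points from the fvnl fraction with a hard zero
below 40 %.  Its default is eight thresholds evenly spaced from 0.40 to
1.00 inclusive: a 100 % fvnl dish (chilled tomatoes) scores exactly 7,
matching the catalog's observed ceiling, and the eighth point opens only
above 100 % — unreachable for non-concentrated dishes, consistent with no
catalog dish printing 8.

Because the interior thresholds of the reconstructed tables cannot be
confirmed against published per-dish nutrient data, validation of raw
nutrient → point conversion rests on the anchored tables (exercised
against a brute-force oracle), on calibration vectors consistent with the
catalog's extreme rows, and on the property suite; the 123 worked rows
validate everything downstream of the component points exactly.

## Cap and aggregation

`protein_capped = 0` when `baseline >= 13` and `V < 5`, else the raw
banded score.  Aggregation is exact integer arithmetic enforced at
construction: `ScoreResult` refuses any instance whose baseline,
modification, or final score deviates from its component points, which
turns every fixture load into a transcription-integrity check.  The cap
makes the final score discontinuous in the restricted amounts: one extra
sodium band that lifts the baseline from 12 to 13 adds the band point
*plus* the entire forfeited protein score.  The soy-sauce ramen scenarios
exhibit the extreme: a 22-point swing between leaving and drinking the
soup.

## Ratings

Within a category, the nine cutpoints are the 10th–90th percentiles of the
final-score distribution by linear interpolation at fractional index
`(n−1)·k/10` (the "type 7" convention).  No quantile algorithm is
published for the model; this convention is adopted because it uniquely
reproduces both the published display-threshold table (after rounding) and
every printed per-dish rating, including the eight catalog scores that sit
exactly on a rounded display threshold — those rows discriminate between
conventions and are asserted individually.  Other numpy quantile methods
sit behind a config switch for sensitivity analysis.

Star assignment uses the **unrounded** cutpoints: a score at or below the
k-th cutpoint earns `5 − 0.5·(k−1)` stars, a score above all nine earns
0.5.  Display thresholds are rounded half-up on the signed value,
implemented as `floor(x + 0.5)` (5.5 → 6, −0.2 → 0, −1.2 → −1); the
rounded integers are presentation only and never feed assignment.
Ratings are relative to the catalog that produced the cutpoints; with
fewer than ten dishes in a category the deciles degenerate (the reference
catalog itself has n = 12 and n = 18 categories whose neighbouring ratings
share thresholds) and the package warns.  Frozen cutpoints can be supplied
to rate new dishes deterministically without recomputing distributions.

## Fixtures

The packaged tables transcribe the published worked examples verbatim: 18
noodle-soup scenario rows (six dishes × left-all / half / all) and the
105-dish catalog (20/34/21/12/18 across the five categories).  Typographic
minus signs are normalised to ASCII on load; glyph ratings parse through
the one-black-star/one-white-half-star mapping.  One catalog row (the
middle white-rice portion) prints a food weight inconsistent with its
portion label; it is stored verbatim with `flagged=typo_suspected` rather
than silently corrected.  The soup scenarios are modelled as linear
mixing, `dish = base + fraction × soup`; the published half-consumed rows
confirm the midpoint exactly for the five soup-in-bowl dishes' food
weights, while total weights deviate by 1–2.5 g (independent per-scenario
rounding in the source nutrient software) and cold soba — a dipped noodle —
is genuinely non-linear.  Tests assert the exact cells and document the
deviations instead of pretending the identity holds where the printed data
contradicts it.

## Synthetic dishes

The generator emulates per-category point-level structure, not recipes.
Each archetype builds an ingredient list satisfying its category's
defining rule by construction (e.g. a side is 75–95 % vegetables by
weight; a mixed dish caps every family below 45 % while meeting both SV
rules), assuming 0.36 g carbohydrate per g cooked grain and 0.20 g protein
per g cooked protein source.  Nutrient amounts are drawn uniformly from
per-category ranges sized to standard Japanese recipes (sides 20–120 kcal
with 100–800 mg sodium; mixed dishes with staple 450–800 kcal with
700–2000 mg) and calibrated once so that a catalog mixed in the reference
proportions lands its overall component-point medians within one point of
the published catalog medians — asserted as a smoke test, not an
acceptance target.  What passing these tests shows is that the pipeline is
internally consistent on realistic magnitudes; it says nothing about real
recipes, whose nutrients are correlated (fat with energy, sodium with
seasoning weight) in ways independent uniform draws are not.  All
randomness flows through a seeded numpy generator; fixed seeds give
bit-identical catalogs.

## Numerical choices and degenerate inputs

Points and aggregates are Python integers throughout; nutrient inputs are
never rounded before lookup.  Weight reconciliation between an ingredient
list and the declared cooked food weight tolerates max(2 g, 2 %).  Empty
ingredient lists are allowed — classification then requires a category
override and V points an explicit fvnl fraction.  Errors are typed:
`SchemaError` for missing columns/keys (naming the column),
`ValidationError` for invariant violations (naming the dish).

## Known limitations

Interior thresholds of the reconstructed band tables are consistent with,
but not uniquely determined by, the published scores; obtaining the full
published score table would let the config's `reconstructed` entries be
replaced without code changes.  Ratings carry no cross-category meaning,
and the model makes no absolute healthiness claim for any score range.
Nutrient computation from raw recipes (food-composition lookup, salt/oil
absorption during cooking) is out of scope: this package starts from
per-dish nutrient amounts.
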