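# npmdj — Nutrient Profile Model for Dishes in Japan (NPM-DJ 1.0)

`npmdj` implements NPM-DJ 1.0, a dish-level nutrient profile model for
public-health nutrition in Japan.  Unlike per-100 g profiling of packaged
foods, NPM-DJ evaluates a *dish* in its as-consumed state — noodles with
their broth, seasoning included — which is how sodium is actually eaten in
Japan.  The package is for nutritionists, food-business operators and
researchers who want to score recipes, explore reformulation scenarios
(e.g. how much a final score improves when the noodle soup is left in the
bowl), or rate dishes within their category.

## The model

Each dish is processed in three stages:

1. **Categorization.** Dishes fall into five categories — staple, side,
   main, mixed, and mixed with staple.  Step 1 assigns a category when one
   food-group family supplies strictly more than 2/3 of the cooked food
   weight (grains → staple; vegetables, potatoes, non-soy legumes,
   mushrooms, seaweed, nuts and seeds → side; meat, fish, eggs, soy →
   main).  Remaining dishes are split in step 2 by serving (SV) tallies
   (1 staple SV = 40 g carbohydrate, 1 side SV = 70 g main ingredient,
   1 main SV = 6 g protein): under 0.5 staple SV with ≥ 0.5 SV of both
   main and side is *mixed*; ≥ 0.5 staple SV with ≥ 0.5 SV of a main or
   side is *mixed with staple*.

2. **Scoring.** Restricted components earn *baseline points* through
   banded tables whose first bands open at 3.75 % of the reference intakes
   (energy: 2200 kcal; sodium: 2756 mg, the 7 g salt target) or at
   energy-relative anchors (saturated fat 7 %E, sugars 10 %E).
   Recommended components earn *modification points*: V points (0–8) for
   the fvnl weight fraction (fruits/vegetables/nuts/legumes/seaweed/seeds/
   mushrooms, potatoes excluded; zero below 40 %), protein points
   (anchored at 3.75 % of the 81 g NRV), and fiber points (3.75 % of
   19 g).  A **protein cap** zeroes the protein score when the baseline is
   ≥ 13 points unless the dish holds ≥ 5 V points.  Then

   ```
   final score = (energy + satfat + sugars + sodium)
               − (V + protein_capped + fiber)
   ```

   Lower is more favourable.

3. **Rating.** Within each category, final scores are cut at their nine
   deciles (linear-interpolation quantiles); a dish earns 5.0 stars down
   to 0.5 stars depending on the first unrounded cutpoint its score does
   not exceed.

The packaged configuration ships the model constants and one band table
per component, each marked `anchored` (fixed by the published anchors) or
`reconstructed` (interior thresholds chosen consistently with every
published worked score; replaceable via a config override).

## Worked example

Score the six-dish noodle-soup experiment that ships with the package —
the same dish scored with the soup left in the bowl versus fully consumed:

```python
import npmdj

config = npmdj.load_model_config()
rows = {r.dish_id: r for r in npmdj.load_fixtures("T3")}

for dish in ("udon", "zaru_soba", "ramen"):
    left = npmdj.score_dish(None, config, precomputed=rows[f"{dish}:left_all"].points)
    drunk = npmdj.score_dish(None, config, precomputed=rows[f"{dish}:all"].points)
    print(f"{dish:10s} left={left.final_score:3d} consumed={drunk.final_score:3d} "
          f"penalty={drunk.final_score - left.final_score}")
```

prints

```
udon       left= 10 consumed= 19 penalty=9
zaru_soba  left= -1 consumed= 11 penalty=12
ramen      left= -2 consumed= 20 penalty=22
```

Leaving ramen soup saves 22 points: drinking it pushes sodium up by 17
bands *and* lifts the baseline past the 13-point protein cap, forfeiting
the dish's 4 protein points at once.  Rate the 105-dish reference catalog
from the shell:

```sh
npm-dj fixtures --table T4 --out t4.csv
npm-dj rate --scores t4.csv --out rated.csv --thresholds-out thresholds.csv
```

`rated.csv` carries a 0.5–5-star rating per dish (e.g. chilled tomatoes,
final score −7, earns ★★★★★ among side dishes; tempura udon with all its
soup, 22, earns ☆) and `thresholds.csv` the per-category display
thresholds.

Scoring your own dishes needs a CSV with per-dish nutrient columns
(`energy_kcal, satfat_g, sugars_g, sodium_mg, protein_g, fiber_g`) plus
weights, and — for classification and V points — an ingredient CSV with
cooked weights and food-group tags (`npm-dj classify`, `npm-dj score`).

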