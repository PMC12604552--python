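# nutriprocure

Tools for scoring food products with the **Nutri-Score 2023** nutrient
profiling algorithm and for auditing school food procurement against the
Norwegian school meal guidelines.

Norwegian high schools are advised to offer healthy canteen food, but the
guidelines are broadly worded and hard to apply product by product. In
Viken County, nutrition experts (Matvalget) classify every procured product
into three categories — *recommended to be offered*, *recommended in
limited amounts*, *not recommended* — and the county tracks the share of
purchase money spent in each category. This package implements the
complementary, fully algorithmic route: compute each product's Nutri-Score
(letters A–E; unfavorable points for energy, sugars, saturated fat and
salt minus favorable points for protein, fiber and fruit/vegetable/legume
content), measure how well the letters agree with the expert categories,
apply food-group-specific acceptable letter ranges, and evaluate per-school
purchase-value goals. It is written for public-health analysts and
procurement auditors working with product lists and purchase ledgers.

## What is inside

| module | what it does |
| --- | --- |
| `nutriprocure.scoring` | Nutri-Score 2023 engine: three algorithm classes (general foods; fats/oils/nuts/seeds; beverages), point tables and cutoffs shipped as a versioned YAML config |
| `nutriprocure.agreement` | letter-vs-category agreement rules, band × category cross tables, five-number score summaries; includes the published Viken cross-tabulation (n = 4,790) as packaged data |
| `nutriprocure.pipeline` | CSV ingestion with reject routing, audited cleaning (dedupe → uncovered → discontinued → supplier filter), Nutri-Score coverage reporting |
| `nutriprocure.policy` | food-group/role-specific acceptable letter ranges (bread toppings up to C, fish toppings and small-quantity ingredients up to D, oil-based dressings exempt, juice ≤ 250 ml) |
| `nutriprocure.goals` | per-school purchase-value shares, the A/B-vs-recommended share regression, and the ≥65 % A–B / ≤15 % unfavorable goal evaluation (unfavorable = E, or C–E for beverages) |
| `nutriprocure.simulate` | seeded synthetic product lists and school ledgers with an exact truth sidecar, emulating the structure of the county procurement data (which are not public) |

The numbered scripts under `analysis/` run the full study on a synthetic
cohort: `01_simulate.py` → `02_score_products.py` → `03_agreement.py` →
`04_range_policy.py` → `05_value_goals.py`, writing tables under
`results/`. A `nutriprocure` command-line interface wraps the same
functions (`simulate`, `score`, `clean`, `coverage`, `agreement`,
`advise`, `goals`).

## The score, briefly

For a general food, unfavorable points N = energy + sugars + saturated fat
+ salt points (caps 10/15/10/20) and favorable points P = protein + fiber +
FVL points (caps 7/5/5); the score is N − P and the letter comes from
cutoffs A ≤ 0 < B ≤ 2 < C ≤ 10 < D ≤ 18 < E. When N ≥ 11, protein is
dropped unless the product is a cheese or FVL points are at their cap; red
meat protein is capped at 2 points. Fats, oils, nuts and seeds replace
energy with energy from saturates and the saturated-fat amount with the
saturated-to-total-fat ratio (letter A shifts to ≤ −6). Beverages use
their own energy/sugar/protein/FVL tables, add 4 points for non-nutritive
sweeteners, and only water can be A.

## Worked example

```python
from nutriprocure.scoring import (NutrientProfile, AlgorithmClass,
                                  compute_score)

choc = NutrientProfile(energy_kj=2353, sugars_g=52, saturated_fat_g=17,
                       salt_g=0.5, protein_g=6, fiber_g=2)
res = compute_score(choc, AlgorithmClass.GENERAL)
print(res.component_points, res.final_score, res.letter)
```

prints

```
{'energy_kj': 7, 'sugars_g': 15, 'saturated_fat_g': 10, 'salt_g': 2,
 'protein_g': 2, 'fiber_g': 0, 'fvl_percent': 0} 34 E
```

— a confectionery-like product collects 34 unfavorable-minus-favorable
points (protein is dropped because N = 34 ≥ 11) and lands in band E.

Running the analysis chain on the default synthetic cohort
(`python analysis/01_simulate.py` … `05_value_goals.py`) prints, among
other lines:

```
guideline category mix (%): {'recommended': 53.0, 'limited': 32.9, 'not_recommended': 14.1}
Nutri-Score letter distribution (%): {'A': 34.0, 'B': 10.0, 'C': 20.3, 'D': 19.8, 'E': 15.9}
synthetic cohort: agreement 65.9%, disagreement 13.5% (n = 4790)
A/B share vs recommended share: slope=0.91 (SE 0.12, p=5.7e-05, n=10); planted slope 0.94
```

i.e. the generated cohort reproduces the intended category mix, most
*recommended* products score A or B, and the per-school regression of A/B
value share on recommended-category value share recovers the planted slope.

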