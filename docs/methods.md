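# Methods

## Scoring model

The engine implements the 2023 revision of the Nutri-Score nutrient
profiling algorithm. Each component's points are a step function of the
nutrient amount per 100 g (foods) or 100 ml (beverages): the points equal
the highest step whose threshold the value *strictly exceeds* (the interval
notation of the published tables is "> a to ≤ b"), except the
saturated-to-total-fat ratio table, whose published intervals are closed
below and therefore uses ≥. Both conventions are declared per table in
`src/nutriprocure/data/nutriscore_2023.yaml`; the engine contains no
numeric thresholds of its own, so the config can be audited — or replaced
by a future revision — without touching code.

Three algorithm classes exist and the class is decided by the product's
food group (Beverages → beverage algorithm; Fats and Nuts → the
fats/oils/nuts/seeds algorithm; the remaining twelve groups → the main
algorithm), with explicit overrides available. An unmapped group is a hard
error: a silent default would corrupt every downstream statistic.

Conditional rules, all encoded in the config:

* main algorithm — protein points are dropped when the negative subtotal
  N ≥ 11, unless the product is a cheese or the fruit/vegetable/legume
  (FVL) component is at its 5-point cap; red meat protein is capped at
  2 points;
* fats/oils/nuts/seeds — total energy is replaced by energy from saturates
  (saturated fat × 37 kJ/g), the saturated-fat amount by the
  saturated-to-total-fat ratio, and the protein-drop threshold is N ≥ 7;
  the A cutoff shifts to score ≤ −6;
* beverages — own energy, sugar, protein and FVL tables, a flat 4-point
  penalty for non-nutritive sweeteners, protein always counted; water is A
  by definition and no other beverage can be A.

The engine takes `fvl_percent` as an input rather than estimating it from
ingredient lists; a missing value defaults to 0, the conservative choice
that never awards unearned favorable points. Salt is canonical; sodium can
be converted with the standard labelling factor 2.5. Whether unflavored
sparkling water counts as "water" is a labelling judgment, so `is_water` is
an explicit input flag, never inferred.

## Agreement analysis

Letters and the three-category guideline classification are paired as:
agree = (recommended, A/B), (limited, C/D), (not recommended, E);
disagree = (recommended, D/E), (limited or not recommended, A/B); the four
remaining pairs are neutral. Cross tables use the reporting bands
A–B / C / D–E. Because the D–E band cannot separate D from E, agreement
for the "limited" category is not derivable from a banded table; agreement
totals are therefore always computed from product-level letters, and the
banded table is authoritative only for disagreement (whose definition uses
whole bands). Column percentages are stored at full precision and rounded
to integers only for display.

The packaged file `data/viken_crosstab.csv` transcribes the published
Viken County cross-tabulation (2021–2023 procurements, n = 4,790) cell by
cell. One printed cell (snacks × limited × D–E, printed 9) is internally
inconsistent with its own row total (which requires 20); the transcription
keeps the printed value and no invariant asserts that per-group cells sum
to the overall rows. All quantities recomputed from this file use only
internally consistent cells.

Five-number score summaries per (category × algorithm class) stratum use
linear-interpolation quantiles on the sorted scores, matching the
brute-force sorted-list definition used as the test oracle.

## Cleaning pipeline

Cleaning runs in the audit's order — duplicate product ids (first
occurrence kept, so results depend only on file order), products outside
Nutri-Score coverage, discontinued products, then a supplier allowlist —
and tallies every removal; `initial − Σ removed = final` is asserted, and
cleaning is idempotent. Purchases referencing unknown or uncovered
products stay in the value totals but are flagged: coverage is reported
(items and value share), not silently discarded. Malformed input rows are
routed to a rejects table with reasons.

## Value shares, regression, goals

Per-school shares are percentages of *covered* purchase value; uncovered
value is reported alongside, never folded into a letter class (the share
denominator therefore matches how the county separates its ~2.5 %
uncovered value). The unfavorable class is letter E, extended to C–E for
beverages, because beverages the guidelines advise against (sweetened and
sweetener-containing drinks, juices in large containers) cluster in C.
Shares are scale invariant in the currency unit.

The relation between the guideline-basis and Nutri-Score-basis shares is
estimated by ordinary least squares (statsmodels) of the A/B value share on
the recommended-category value share across schools, with a two-sided
slope p-value; fewer than 3 schools or zero variance in the regressor is a
hard error. The published goal correspondence (guideline goal ≥70 % / ≤8 %
↔ Nutri-Score goal ≥65 % / ≤15 %) is shipped as constants
(`GUIDELINE_GOALS`, `NUTRISCORE_GOALS`) because the intercepts behind the
original mapping are not recoverable without the original ledgers; the
machinery to re-derive such a mapping on any dataset is
`fit_share_regression` plus `predict_favorable_goal` (inverse prediction
along the fitted line). Goal bounds are inclusive.

## Range policy

The default policy accepts A and B everywhere and encodes the food-group
amendments as ordered first-match-wins rules over role metadata: bread
toppings up to C, fish-based bread toppings and small-quantity ingredients
(dressings, reduced-fat cream, mayonnaise) up to D, oil-based salad
dressings exempt from the E ban, juice up to C only in portions ≤ 250 ml.
Roles and portion sizes are inputs: assigning them is procurement judgment,
not something inferable from nutrient data. A product matching a
portion-capped rule without a known portion gets a `conditional` verdict.
The whole-grain preference for bread, grains and pasta/rice is not
expressible as a letter range and is attached as an advisory annotation
driven by a `whole_grain` flag, never a verdict change.

## Synthetic data generator

The generator emulates the *structure and statistical features* of county
procurement data, which are not publicly available: ≈4,790 products across
14 food groups (group weights proportional to the published group sizes),
a 53/33/14 category mix, 10 schools of which 5 received dietary guidance,
≈2.5 % of purchase value outside Nutri-Score coverage, and a planted
linear relation with slope 0.94 between a school's recommended-category
value share and its A/B value share.

Nutrient marginals per group are lognormal bodies (nonnegative,
right-skewed) truncated to [0, 100] g, with per-group medians and
dispersions chosen once as plausible per-100 g values for Norwegian canteen
assortments (documented in `GROUP_NUTRIENTS`); energy is truncated normal,
fats draw a total-fat level and a saturates ratio so the profile invariant
saturated ≤ total holds by construction. The guideline category is
assigned from a latent quality score (low energy/sugars/saturated
fat/salt, high fiber/FVL), rank-transformed to standard normal, mixed with
independent noise through a coupling parameter κ (default 0.85; κ = 0
makes categories independent of nutrients), and cut at the normal quantiles
of the target mix — so the category mix is calibrated regardless of κ and
the category–letter correlation is a single interpretable knob.

Ledgers are built to realize per-school share targets: each school draws a
target recommended share (guided and unguided schools have different
centres), a target A/B share from the planted line plus noise, and value is
allocated across category × letter-band cells (scaling the cohort's
within-category A/B composition) before sampling products within each
cell. All line values are integer NOK, so sums are exact in floating point
in any order; the truth sidecar tallies the realized shares with integer
arithmetic at generation time, which is why pipeline-recomputed shares are
asserted *equal*, not approximately equal. The planted slope is a target
realized through noisy per-school targets, so slope recovery is a genuine
statistical check, not bookkeeping.

What the generator does not emulate: real supplier catalogues and price
levels, within-group nutrient correlations beyond the latent quality
score, expert judgment quirks (e.g. portion-aware classifications), and
seasonal purchasing. Passing tests therefore demonstrate the pipeline's
correctness and calibration on data with the study's structure — not that
the published agreement level would be reproduced on the proprietary
records.

## Problem sizes and determinism

Default analysis and acceptance runs use the full study scale (4,790
products, 10 schools), which completes in a few seconds. The slope-recovery
test uses 40 schools with reduced target noise so the 3-standard-error
criterion has power; the guidance-effect test averages 8 seeds. All
randomness flows from `numpy.random.default_rng` seeded by the single
`seed` field (the ledger stream derives from it via a SeedSequence), so
every output is reproducible byte for byte per seed.
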