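"""Nutri-Score 2023 scoring engine.

The Nutri-Score is a five-letter (A best, E worst) front-of-pack nutrient
profiling label.  Unfavorable ("negative") points are awarded for energy,
sugars, saturated fat and salt, favorable ("positive") points for protein,
fiber and fruit/vegetable/legume (FVL) content; the final score is the
difference N - P (lower is healthier), mapped to a letter through
class-specific cutoffs.  The 2023 revision uses three distinct algorithms:

* the main algorithm for general foods,
* the algorithm for fats, oils, nuts and seeds (energy from saturates
  replaces total energy; the saturated-to-total-fat ratio replaces the
  saturated-fat amount),
* the algorithm for beverages (its own energy/sugar/protein/FVL tables, a
  flat penalty for non-nutritive sweeteners, and water pinned at A).

All point tables and cutoffs are data, not code: they live in the versioned
config ``data/nutriscore_2023.yaml`` so the engine is auditable line by line
against the published tables and a future revision can be swapped in.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd
import yaml

KCAL_TO_KJ = 4.184
#: kJ of energy per gram of fat (used for energy-from-saturates)
KJ_PER_G_FAT = 37.0
#: labelling convention: salt (g) = sodium (g) x 2.5
SODIUM_TO_SALT = 2.5

LETTERS = ("A", "B", "C", "D", "E")


class ScoringError(ValueError):
    """A product cannot be scored (missing field, unmapped group, ...)."""


class AlgorithmClass(enum.Enum):
    GENERAL = "general"
    FATS_OILS_NUTS_SEEDS = "fats_oils_nuts_seeds"
    BEVERAGE = "beverage"


#: default mapping from the 14 procurement food groups to algorithm classes;
#: anything not listed falls to the main (general) algorithm explicitly.
DEFAULT_GROUP_ALGORITHM = {
    "Fruits and vegetables": AlgorithmClass.GENERAL,
    "Grains": AlgorithmClass.GENERAL,
    "Bread": AlgorithmClass.GENERAL,
    "Pasta and rice": AlgorithmClass.GENERAL,
    "Red meat": AlgorithmClass.GENERAL,
    "White meat": AlgorithmClass.GENERAL,
    "Fish and seafood": AlgorithmClass.GENERAL,
    "Ready meals": AlgorithmClass.GENERAL,
    "Sauces and dressings": AlgorithmClass.GENERAL,
    "Dairy products and eggs": AlgorithmClass.GENERAL,
    "Fats": AlgorithmClass.FATS_OILS_NUTS_SEEDS,
    "Nuts": AlgorithmClass.FATS_OILS_NUTS_SEEDS,
    "Snacks": AlgorithmClass.GENERAL,
    "Beverages": AlgorithmClass.BEVERAGE,
}

FOOD_GROUPS = tuple(DEFAULT_GROUP_ALGORITHM)


@dataclass(frozen=True)
class NutrientProfile:
    """Nutrient content of one product per 100 g (foods) or 100 ml (beverages).

    ``fvl_percent`` is the estimated fruit/vegetable/legume proportion;
    ``total_fat_g`` is required only for the fats/oils/nuts/seeds class,
    ``has_nonnutritive_sweeteners`` only matters for beverages.
    """

    energy_kj: float
    sugars_g: float
    saturated_fat_g: float
    salt_g: float
    protein_g: float
    fiber_g: float
    fvl_percent: float = 0.0
    total_fat_g: float | None = None
    has_nonnutritive_sweeteners: bool = False
    is_water: bool = False

    def __post_init__(self) -> None:
        for name in ("energy_kj", "sugars_g", "saturated_fat_g", "salt_g",
                     "protein_g", "fiber_g", "fvl_percent"):
            v = getattr(self, name)
            if not (v >= 0):  # also catches NaN
                raise ScoringError(f"{name} must be >= 0, got {v!r}")
        for name in ("sugars_g", "saturated_fat_g", "salt_g",
                     "protein_g", "fiber_g"):
            if getattr(self, name) > 100:
                raise ScoringError(f"{name} cannot exceed 100 g per 100 g")
        if self.fvl_percent > 100:
            raise ScoringError("fvl_percent must lie in [0, 100]")
        if self.total_fat_g is not None:
            if not (0 <= self.total_fat_g <= 100):
                raise ScoringError("total_fat_g must lie in [0, 100]")
            if self.saturated_fat_g > self.total_fat_g + 1e-9:
                raise ScoringError("saturated_fat_g cannot exceed total_fat_g")


@dataclass(frozen=True)
class ScoringFlags:
    """Product attributes that alter the protein rule of the main algorithm."""

    is_red_meat: bool = False
    is_cheese: bool = False


@dataclass(frozen=True)
class PointTable:
    """One component's step function: points = steps exceeded, capped.

    ``mode`` is ``"gt"`` (a step is earned when value > threshold) for every
    published table except the saturates ratio, which uses ``"ge"``.
    """

    component: str
    steps: tuple[tuple[float, int], ...]
    cap: int
    mode: str = "gt"

    def __post_init__(self) -> None:
        thresholds = [t for t, _ in self.steps]
        points = [p for _, p in self.steps]
        if thresholds != sorted(set(thresholds)):
            raise ValueError(f"{self.component}: thresholds must increase strictly")
        if points != sorted(points):
            raise ValueError(f"{self.component}: points must be non-decreasing")
        if points and points[-1] != self.cap:
            raise ValueError(f"{self.component}: last step must reach the cap")
        if self.mode not in ("gt", "ge"):
            raise ValueError(f"{self.component}: unknown mode {self.mode!r}")

    def lookup(self, value: float) -> int:
        if not (value >= 0):
            raise ScoringError(f"{self.component}: value must be >= 0, got {value!r}")
        pts = 0
        for threshold, step_pts in self.steps:
            hit = value >= threshold if self.mode == "ge" else value > threshold
            if hit:
                pts = step_pts
            else:
                break
        return pts


@dataclass(frozen=True)
class NutriScoreResult:
    algorithm_class: AlgorithmClass
    component_points: Mapping[str, int]
    negative_subtotal: int
    positive_subtotal: int
    final_score: int
    letter: str
    protein_counted: bool = True


@dataclass(frozen=True)
class ScoringConfig:
    """Parsed point-table config for all three algorithm classes."""

    version: str
    negative: Mapping[AlgorithmClass, Mapping[str, PointTable]]
    positive: Mapping[AlgorithmClass, Mapping[str, PointTable]]
    protein_rules: Mapping[AlgorithmClass, Mapping]
    cutoffs: Mapping[AlgorithmClass, Mapping[str, int]]
    sweetener_points: int = 4
    group_algorithm: Mapping[str, AlgorithmClass] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_ALGORITHM))


def _parse_tables(section: Mapping) -> dict[str, PointTable]:
    out = {}
    for name, spec in section.items():
        out[name] = PointTable(
            component=name,
            steps=tuple((float(t), int(p)) for t, p in spec["steps"]),
            cap=int(spec["cap"]),
            mode=spec.get("mode", "gt"),
        )
    return out


def load_config(path: str | None = None) -> ScoringConfig:
    """Load the point-table config; the packaged ``nutriscore-2023`` by default."""
    if path is None:
        text = (resources.files("nutriprocure.data") / "nutriscore_2023.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    negative, positive, rules, cutoffs = {}, {}, {}, {}
    for cls in AlgorithmClass:
        sec = raw[cls.value]
        negative[cls] = _parse_tables(sec["negative"])
        positive[cls] = _parse_tables(sec["positive"])
        rules[cls] = sec.get("protein_rule")
        cutoffs[cls] = {k: int(v) for k, v in sec["cutoffs"].items()}
    return ScoringConfig(
        version=raw["version"],
        negative=negative,
        positive=positive,
        protein_rules=rules,
        cutoffs=cutoffs,
        sweetener_points=int(raw["beverage"].get("sweetener_points", 4)),
    )


_DEFAULT_CONFIG: ScoringConfig | None = None


def default_config() -> ScoringConfig:
    global _DEFAULT_CONFIG
    if _DEFAULT_CONFIG is None:
        _DEFAULT_CONFIG = load_config()
    return _DEFAULT_CONFIG


def convert_energy(kcal: float) -> float:
    """kcal -> kJ (1 kcal = 4.184 kJ)."""
    if not (kcal >= 0):
        raise ScoringError(f"energy must be >= 0 kcal, got {kcal!r}")
    return kcal * KCAL_TO_KJ


def salt_from_sodium(sodium_g: float) -> float:
    """Sodium (g) -> salt equivalent (g) via the 2.5 labelling factor."""
    if not (sodium_g >= 0):
        raise ScoringError(f"sodium must be >= 0, got {sodium_g!r}")
    return sodium_g * SODIUM_TO_SALT


def select_algorithm(food_group: str,
                     overrides: Mapping[str, AlgorithmClass] | None = None,
                     config: ScoringConfig | None = None) -> AlgorithmClass:
    """Map a food-group label (plus explicit overrides) to an algorithm class.

    An unmapped group raises :class:`ScoringError` rather than silently
    defaulting — misclassification would corrupt every downstream score.
    """
    if overrides and food_group in overrides:
        return overrides[food_group]
    mapping = (config or default_config()).group_algorithm
    try:
        return mapping[food_group]
    except KeyError:
        raise ScoringError(
            f"food group {food_group!r} has no algorithm mapping and no override"
        ) from None


def component_points(value: float, table: PointTable) -> int:
    """Points for one component: number of table steps the value exceeds."""
    return table.lookup(value)


def score_to_letter(score: int, cls: AlgorithmClass, is_water: bool = False,
                    config: ScoringConfig | None = None) -> str:
    """Map a final score to a letter via the class-specific cutoffs.

    Water is pinned at A regardless of score; other beverages cannot
    score better than B.
    """
    cutoffs = (config or default_config()).cutoffs[cls]
    if cls is AlgorithmClass.BEVERAGE and is_water:
        return "A"
    for letter in LETTERS:
        if letter in cutoffs and score <= cutoffs[letter]:
            return letter
    return "E"


def compute_score(profile: NutrientProfile, cls: AlgorithmClass,
                  flags: ScoringFlags = ScoringFlags(),
                  config: ScoringConfig | None = None) -> NutriScoreResult:
    """Score one product under the given algorithm class.

    Applies the class-specific component set, the conditional protein rule
    (protein dropped at high negative subtotals, with cheese and max-FVL
    exemptions and a red-meat cap), and the beverage sweetener penalty.
    """
    cfg = config or default_config()
    neg_tables = cfg.negative[cls]
    pos_tables = cfg.positive[cls]
    pts: dict[str, int] = {}

    for name, table in neg_tables.items():
        if name == "energy_from_saturates_kj":
            value = profile.saturated_fat_g * KJ_PER_G_FAT
        elif name == "saturates_ratio_percent":
            if profile.total_fat_g is None:
                raise ScoringError(
                    "total_fat_g is required for the fats/oils/nuts/seeds algorithm")
            value = (0.0 if profile.total_fat_g == 0
                     else 100.0 * profile.saturated_fat_g / profile.total_fat_g)
        else:
            value = getattr(profile, name)
        pts[name] = table.lookup(value)

    if cls is AlgorithmClass.BEVERAGE:
        pts["sweeteners"] = (cfg.sweetener_points
                             if profile.has_nonnutritive_sweeteners else 0)

    negative = sum(pts[name] for name in pts)

    for name, table in pos_tables.items():
        pts[name] = table.lookup(getattr(profile, name))

    rule = cfg.protein_rules[cls]
    protein_counted = True
    if rule is not None:
        if flags.is_red_meat:
            pts["protein_g"] = min(pts["protein_g"], int(rule["red_meat_protein_cap"]))
        fvl_at_cap = pts["fvl_percent"] == pos_tables["fvl_percent"].cap
        if negative >= int(rule["negative_threshold"]):
            exempt = ((rule.get("cheese_exempt") and flags.is_cheese)
                      or (rule.get("fvl_max_exempt") and fvl_at_cap))
            if not exempt:
                protein_counted = False

    positive = (pts["fiber_g"] + pts["fvl_percent"]
                + (pts["protein_g"] if protein_counted else 0))
    score = negative - positive
    letter = score_to_letter(score, cls, is_water=profile.is_water, config=cfg)
    return NutriScoreResult(
        algorithm_class=cls,
        component_points=pts,
        negative_subtotal=negative,
        positive_subtotal=positive,
        final_score=score,
        letter=letter,
        protein_counted=protein_counted,
    )


# ---------------------------------------------------------------------------
# DataFrame front end

#: columns appended by :func:`score_products_frame`
SCORE_COLUMNS = ("algorithm", "negative_points", "positive_points",
                 "nutri_score", "nutri_letter")


def profile_from_row(row: Mapping) -> NutrientProfile:
    return NutrientProfile(
        energy_kj=float(row["energy_kj"]),
        sugars_g=float(row["sugars_g"]),
        saturated_fat_g=float(row["saturated_fat_g"]),
        salt_g=float(row["salt_g"]),
        protein_g=float(row["protein_g"]),
        fiber_g=float(row["fiber_g"]),
        fvl_percent=float(row.get("fvl_percent", 0.0) or 0.0),
        total_fat_g=(float(row["total_fat_g"])
                     if row.get("total_fat_g") is not None
                     and not pd.isna(row.get("total_fat_g")) else None),
        has_nonnutritive_sweeteners=bool(row.get("has_nonnutritive_sweeteners", False)),
        is_water=bool(row.get("is_water", False)),
    )


def score_products_frame(products: pd.DataFrame,
                         config: ScoringConfig | None = None) -> pd.DataFrame:
    """Score every row of a products table.

    Expects the nutrient columns of :func:`profile_from_row` plus
    ``food_group`` and the optional flag columns ``is_red_meat`` /
    ``is_cheese``.  Returns a copy with :data:`SCORE_COLUMNS` appended.
    """
    cfg = config or default_config()
    out = products.copy()
    algs, negs, poss, scores, letters = [], [], [], [], []
    for row in products.to_dict("records"):
        cls = select_algorithm(str(row["food_group"]), config=cfg)
        flags = ScoringFlags(is_red_meat=bool(row.get("is_red_meat", False)),
                             is_cheese=bool(row.get("is_cheese", False)))
        res = compute_score(profile_from_row(row), cls, flags, config=cfg)
        algs.append(cls.value)
        negs.append(res.negative_subtotal)
        poss.append(res.positive_subtotal)
        scores.append(res.final_score)
        letters.append(res.letter)
    out["algorithm"] = algs
    out["negative_points"] = negs
    out["positive_points"] = poss
    out["nutri_score"] = scores
    out["nutri_letter"] = letters
    return out
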