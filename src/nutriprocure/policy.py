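"""Food-group-specific acceptable Nutri-Score ranges for procurement advice.

The default policy accepts letters A and B everywhere, with ordered override
rules for roles where the school meal guidelines tolerate worse letters
(bread toppings, small portions of juice, small-quantity ingredients,
oil-based salad dressings).  Roles and portion sizes are input metadata —
assigning them requires the judgment of the procurer, not inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import pandas as pd
import yaml

from .scoring import LETTERS, FOOD_GROUPS


class PolicyError(ValueError):
    """Malformed policy configuration."""


@dataclass(frozen=True)
class PolicyRule:
    rule_id: str
    letters: frozenset[str]
    citation: str
    food_group: str | None = None
    role: str | None = None
    max_portion_ml: float | None = None

    def matches(self, food_group: str, role: str | None,
                portion_ml: float | None) -> bool:
        if self.food_group is not None and food_group != self.food_group:
            return False
        if self.role is not None and role != self.role:
            return False
        if self.max_portion_ml is not None:
            if portion_ml is None or portion_ml > self.max_portion_ml:
                return False
        return True


@dataclass(frozen=True)
class RangePolicy:
    """Ordered override rules over a default acceptable-letter set."""

    name: str
    default_letters: frozenset[str]
    rules: tuple[PolicyRule, ...] = ()
    whole_grain_groups: frozenset[str] = frozenset()
    whole_grain_note: str = ""


@dataclass(frozen=True)
class ProcurementAdvice:
    verdict: str  # acceptable | conditional | avoid
    rule_id: str
    rationale: str
    advisory: str = ""


def _check_letters(letters, where: str) -> frozenset[str]:
    letters = frozenset(letters)
    bad = letters - set(LETTERS)
    if bad:
        raise PolicyError(f"{where}: unknown Nutri-Score letter(s) {sorted(bad)}")
    return letters


def load_policy(path: str | None = None) -> RangePolicy:
    """Load a range policy; the packaged school default when no path given."""
    if path is None:
        src = (resources.files("nutriprocure.data")
               / "policy" / "nutriscore-2023-school.yaml").read_text()
    else:
        with open(path) as fh:
            src = fh.read()
    raw = yaml.safe_load(src)
    rules = []
    for spec in raw.get("rules", []):
        match: Mapping = spec.get("match", {})
        group = match.get("food_group")
        if group is not None and group not in FOOD_GROUPS:
            raise PolicyError(f"rule {spec.get('id')!r}: unknown food group {group!r}")
        rules.append(PolicyRule(
            rule_id=str(spec["id"]),
            letters=_check_letters(spec["letters"], f"rule {spec['id']!r}"),
            citation=str(spec.get("citation", "")),
            food_group=group,
            role=match.get("role"),
            max_portion_ml=(float(match["max_portion_ml"])
                            if "max_portion_ml" in match else None),
        ))
    wg = raw.get("whole_grain_advisory", {})
    return RangePolicy(
        name=str(raw.get("name", "custom")),
        default_letters=_check_letters(raw.get("default_letters", ["A", "B"]),
                                       "default_letters"),
        rules=tuple(rules),
        whole_grain_groups=frozenset(wg.get("food_groups", [])),
        whole_grain_note=str(wg.get("note", "")),
    )


def empty_policy() -> RangePolicy:
    """A policy with no overrides: acceptable iff letter is A or B."""
    return RangePolicy(name="default-only", default_letters=frozenset({"A", "B"}))


def evaluate_product(letter: str, food_group: str, policy: RangePolicy,
                     role: str | None = None,
                     portion_ml: float | None = None,
                     whole_grain: bool = False) -> ProcurementAdvice:
    """Advise on one scored product.  The first matching rule decides;
    the default letter set applies when no rule matches.

    A rule with a portion cap whose product lacks a portion size yields a
    ``conditional`` verdict (acceptable only once the portion is confirmed).
    """
    if letter not in LETTERS:
        raise PolicyError(f"unknown Nutri-Score letter {letter!r}")
    advisory = ""
    if (food_group in policy.whole_grain_groups) and not whole_grain:
        advisory = policy.whole_grain_note

    for rule in policy.rules:
        portion_pending = (rule.max_portion_ml is not None and portion_ml is None
                           and (rule.role is None or rule.role == role)
                           and (rule.food_group is None or rule.food_group == food_group))
        if rule.matches(food_group, role, portion_ml):
            verdict = "acceptable" if letter in rule.letters else "avoid"
            return ProcurementAdvice(verdict, rule.rule_id, rule.citation, advisory)
        if portion_pending and letter in rule.letters \
                and letter not in policy.default_letters:
            return ProcurementAdvice("conditional", rule.rule_id,
                                     rule.citation + " (portion size unknown)",
                                     advisory)
    verdict = "acceptable" if letter in policy.default_letters else "avoid"
    return ProcurementAdvice(verdict, "default",
                             "default range: letters "
                             + "".join(sorted(policy.default_letters)), advisory)


def advise_frame(products: pd.DataFrame, policy: RangePolicy) -> pd.DataFrame:
    """Per-product verdicts for a scored products table."""
    out = products.copy()
    verdicts, rule_ids, rationales, advisories = [], [], [], []
    for row in products.to_dict("records"):
        portion = row.get("portion_ml")
        adv = evaluate_product(
            letter=str(row["nutri_letter"]),
            food_group=str(row["food_group"]),
            policy=policy,
            role=(None if pd.isna(row.get("role")) else str(row.get("role"))),
            portion_ml=(None if portion is None or pd.isna(portion)
                        else float(portion)),
            whole_grain=bool(row.get("whole_grain", False)),
        )
        verdicts.append(adv.verdict)
        rule_ids.append(adv.rule_id)
        rationales.append(adv.rationale)
        advisories.append(adv.advisory)
    out["verdict"] = verdicts
    out["rule_id"] = rule_ids
    out["rationale"] = rationales
    out["advisory"] = advisories
    return out
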