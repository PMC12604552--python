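"""Scoring-engine tests: point lookups against published anchors, letter
cutoffs, the conditional protein rules, and equivalence with an independent
brute-force scorer that re-encodes the 2023 tables as literal lists."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nutriprocure.scoring import (
    AlgorithmClass, NutrientProfile, ScoringError, ScoringFlags,
    component_points, compute_score, convert_energy, default_config,
    salt_from_sodium, score_to_letter, select_algorithm,
)

from conftest import random_profiles

CFG = default_config()
GEN = AlgorithmClass.GENERAL
FATS = AlgorithmClass.FATS_OILS_NUTS_SEEDS
BEV = AlgorithmClass.BEVERAGE


# --------------------------------------------------------------------------
# independent brute-force oracle: literal tables, scanned step by step

def _steps(first, step, n):
    return [(round(first + i * step, 10), i + 1) for i in range(n)]


ORACLE = {
    GEN: {
        "neg": {
            "energy": _steps(335, 335, 10),
            "sugars": [(3.4, 1), (6.8, 2), (10, 3), (14, 4), (17, 5), (20, 6),
                       (24, 7), (27, 8), (31, 9), (34, 10), (37, 11), (41, 12),
                       (44, 13), (48, 14), (51, 15)],
            "satfat": _steps(1, 1, 10),
            "salt": _steps(0.2, 0.2, 20),
        },
        "protein": [(2.4, 1), (4.8, 2), (7.2, 3), (9.6, 4), (12, 5), (14, 6), (17, 7)],
        "fiber": [(3.0, 1), (4.1, 2), (5.2, 3), (6.3, 4), (7.4, 5)],
        "fvl": [(40, 1), (60, 2), (80, 5)],
        "protein_drop_at": 11,
        "cut": [("A", 0), ("B", 2), ("C", 10), ("D", 18)],
    },
    BEV: {
        "neg": {
            "energy": [(30, 1), (90, 2), (150, 3), (210, 4), (240, 5), (270, 6),
                       (300, 7), (330, 8), (360, 9), (390, 10)],
            "sugars": [(0.5, 1), (2, 2), (3.5, 3), (5, 4), (6, 5), (7, 6),
                       (8, 7), (9, 8), (10, 9), (11, 10)],
            "satfat": _steps(1, 1, 10),
            "salt": _steps(0.2, 0.2, 20),
        },
        "protein": [(1.2, 1), (1.5, 2), (1.8, 3), (2.1, 4), (2.4, 5), (2.7, 6), (3.0, 7)],
        "fiber": [(3.0, 1), (4.1, 2), (5.2, 3), (6.3, 4), (7.4, 5)],
        "fvl": [(40, 2), (60, 4), (80, 6)],
        "protein_drop_at": None,
        "cut": [("B", 2), ("C", 6), ("D", 9)],
    },
}


def _scan(value, steps, ge=False):
    pts = 0
    for threshold, p in steps:
        if (value >= threshold) if ge else (value > threshold):
            pts = p
    return pts


def oracle_score(profile: NutrientProfile, cls: AlgorithmClass,
                 flags: ScoringFlags = ScoringFlags()):
    if cls is FATS:
        neg = (_scan(profile.saturated_fat_g * 37.0, _steps(120, 120, 10))
               + _scan(profile.sugars_g, ORACLE[GEN]["neg"]["sugars"])
               + _scan(0 if profile.total_fat_g == 0 else
                       100 * profile.saturated_fat_g / profile.total_fat_g,
                       [(10, 1), (16, 2), (22, 3), (28, 4), (34, 5), (40, 6),
                        (46, 7), (52, 8), (58, 9), (64, 10)], ge=True)
               + _scan(profile.salt_g, ORACLE[GEN]["neg"]["salt"]))
        t = ORACLE[GEN]
        drop_at = 7
        cut = [("A", -6), ("B", 2), ("C", 10), ("D", 18)]
    else:
        t = ORACLE[cls]
        neg = (_scan(profile.energy_kj, t["neg"]["energy"])
               + _scan(profile.sugars_g, t["neg"]["sugars"])
               + _scan(profile.saturated_fat_g, t["neg"]["satfat"])
               + _scan(profile.salt_g, t["neg"]["salt"]))
        if cls is BEV and profile.has_nonnutritive_sweeteners:
            neg += 4
        drop_at = t["protein_drop_at"]
        cut = t["cut"]
    protein = _scan(profile.protein_g, t["protein"])
    if flags.is_red_meat and cls is not BEV:  # red-meat cap is a food rule
        protein = min(protein, 2)
    fiber = _scan(profile.fiber_g, t["fiber"])
    fvl = _scan(profile.fvl_percent, t["fvl"])
    fvl_max = fvl == t["fvl"][-1][1]
    if drop_at is not None and neg >= drop_at and not flags.is_cheese and not fvl_max:
        protein = 0
    score = neg - (protein + fiber + fvl)
    if cls is BEV and profile.is_water:
        return score, "A"
    for letter, bound in cut:
        if score <= bound:
            return score, letter
    return score, "E"


# --------------------------------------------------------------------------

@pytest.mark.parametrize("value,component,cls,expected", [
    (10.0, "salt_g", GEN, 20),          # published cap: salt up to 20 points
    (50.0, "saturated_fat_g", GEN, 10),  # published cap: sat fat up to 10
    (0.1, "salt_g", GEN, 0),            # below first threshold
    (0.2, "salt_g", GEN, 0),            # boundary: strict > earns nothing
    (0.21, "salt_g", GEN, 1),
    (3350.0, "energy_kj", GEN, 9),
    (3350.1, "energy_kj", GEN, 10),
])
def test_component_points_against_published_anchors(value, component, cls, expected):
    assert component_points(value, CFG.negative[cls][component]) == expected


def test_component_caps_match_published_weighting():
    assert CFG.negative[GEN]["salt_g"].cap == 20
    assert CFG.negative[GEN]["saturated_fat_g"].cap == 10


def test_zero_profile_scores_zero_and_letter_a():
    res = compute_score(NutrientProfile(0, 0, 0, 0, 0, 0), GEN)
    assert res.final_score == 0
    assert all(v == 0 for v in res.component_points.values())
    assert res.letter == "A"


def test_confectionery_profile_gets_e():
    # energy, sugars and sat fat at or near their caps force the worst band
    choc = NutrientProfile(energy_kj=2353, sugars_g=52, saturated_fat_g=17,
                           salt_g=0.5, protein_g=6, fiber_g=2)
    res = compute_score(choc, GEN)
    assert res.letter == "E"
    assert res.final_score >= 19
    # verified by hand against the tables: 7 + 15 + 10 + 2, protein dropped
    assert res.final_score == 34
    assert not res.protein_counted


def test_water_is_always_a():
    water = NutrientProfile(0, 0, 0, 0, 0, 0, is_water=True)
    assert compute_score(water, BEV).letter == "A"
    assert score_to_letter(25, BEV, is_water=True) == "A"


def test_nonwater_beverage_cannot_reach_a():
    assert score_to_letter(-5, BEV) == "B"
    assert score_to_letter(10, BEV) == "E"


@pytest.mark.parametrize("score,letter", [
    (-1, "A"), (0, "A"), (1, "B"), (2, "B"), (3, "C"),
    (10, "C"), (11, "D"), (18, "D"), (19, "E"), (100, "E"),
])
def test_general_cutoff_boundaries(score, letter):
    assert score_to_letter(score, GEN) == letter


def test_fats_class_has_shifted_a_cutoff():
    assert score_to_letter(-6, FATS) == "A"
    assert score_to_letter(-5, FATS) == "B"


def test_sweetener_penalty_only_for_beverages():
    sweet = NutrientProfile(0, 0, 0, 0, 0, 0, has_nonnutritive_sweeteners=True)
    assert compute_score(sweet, BEV).component_points["sweeteners"] == 4
    assert "sweeteners" not in compute_score(sweet, GEN).component_points


def test_red_meat_protein_cap():
    meat = NutrientProfile(700, 0.5, 3, 1.0, 20, 0)
    free = compute_score(meat, GEN, ScoringFlags())
    capped = compute_score(meat, GEN, ScoringFlags(is_red_meat=True))
    assert free.component_points["protein_g"] == 7
    assert capped.component_points["protein_g"] == 2
    assert capped.final_score == free.final_score + 5


def test_cheese_keeps_protein_at_high_negative_points():
    cheese = NutrientProfile(1600, 1, 22, 1.8, 25, 0)
    plain = compute_score(cheese, GEN, ScoringFlags())
    as_cheese = compute_score(cheese, GEN, ScoringFlags(is_cheese=True))
    assert plain.negative_subtotal >= 11
    assert not plain.protein_counted
    assert as_cheese.protein_counted
    assert as_cheese.final_score < plain.final_score


def test_max_fvl_keeps_protein_at_high_negative_points():
    salty_legume = NutrientProfile(800, 2, 1, 4.0, 9, 5, fvl_percent=90)
    res = compute_score(salty_legume, GEN)
    assert res.negative_subtotal >= 11
    assert res.protein_counted


def test_missing_total_fat_raises_for_fats_class():
    oil = NutrientProfile(3700, 0, 10, 0, 0, 0)
    with pytest.raises(ScoringError, match="total_fat_g"):
        compute_score(oil, FATS)


@pytest.mark.parametrize("group,expected", [
    ("Beverages", BEV),
    ("Fats", FATS),
    ("Nuts", FATS),
    ("Bread", GEN),
    ("Snacks", GEN),
])
def test_select_algorithm_mapping(group, expected):
    assert select_algorithm(group) is expected


def test_select_algorithm_rejects_unmapped_group():
    with pytest.raises(ScoringError, match="Herbs"):
        select_algorithm("Herbs and spices")
    assert select_algorithm("Herbs and spices",
                            overrides={"Herbs and spices": GEN}) is GEN


def test_invalid_profiles_rejected():
    with pytest.raises(ScoringError):
        NutrientProfile(-1, 0, 0, 0, 0, 0)
    with pytest.raises(ScoringError):
        NutrientProfile(0, 0, 5, 0, 0, 0, total_fat_g=2)  # satfat > total fat
    with pytest.raises(ScoringError):
        NutrientProfile(0, 0, 0, 0, 0, 0, fvl_percent=120)


def test_energy_conversion():
    assert convert_energy(0) == 0
    assert convert_energy(100) == pytest.approx(418.4)
    assert convert_energy(250) / 4.184 == pytest.approx(250)
    with pytest.raises(ScoringError):
        convert_energy(-1)
    assert salt_from_sodium(0.4) == pytest.approx(1.0)


@settings(max_examples=60, deadline=None, derandomize=True, database=None)
@given(sugars=st.floats(0, 50), extra=st.floats(0.1, 40))
def test_more_sugar_never_improves_score(sugars, extra):
    base = NutrientProfile(800, sugars, 2, 0.5, 5, 2)
    sweeter = dataclasses.replace(base, sugars_g=min(100.0, sugars + extra))
    assert (compute_score(sweeter, GEN).final_score
            >= compute_score(base, GEN).final_score)


@settings(max_examples=60, deadline=None, derandomize=True, database=None)
@given(fiber=st.floats(0, 8), extra=st.floats(0.1, 10), fvl=st.floats(0, 70))
def test_fiber_and_fvl_never_worsen_score(fiber, extra, fvl):
    base = NutrientProfile(1500, 10, 3, 1.0, 5, fiber, fvl_percent=fvl)
    better = dataclasses.replace(base, fiber_g=min(100.0, fiber + extra),
                                 fvl_percent=min(100.0, fvl + 20))
    assert (compute_score(better, GEN).final_score
            <= compute_score(base, GEN).final_score)


def test_letter_is_monotone_step_function_of_score():
    for cls in (GEN, FATS, BEV):
        letters = [score_to_letter(s, cls) for s in range(-20, 41)]
        assert letters == sorted(letters)


@pytest.mark.parametrize("cls,beverage,with_fat", [
    (GEN, False, False), (FATS, False, True), (BEV, True, False),
])
def test_engine_matches_bruteforce_oracle(cls, beverage, with_fat):
    """>=100 randomized profiles per class against the independent scorer."""
    rng = np.random.default_rng(2024)
    profiles = random_profiles(rng, 150, beverage=beverage, with_total_fat=with_fat)
    flag_sets = [ScoringFlags(), ScoringFlags(is_red_meat=True),
                 ScoringFlags(is_cheese=True)]
    for i, profile in enumerate(profiles):
        flags = flag_sets[i % 3]
        res = compute_score(profile, cls, flags)
        exp_score, exp_letter = oracle_score(profile, cls, flags)
        assert res.final_score == exp_score, (profile, flags)
        assert res.letter == exp_letter, (profile, flags)
        caps = {**{k: t.cap for k, t in CFG.negative[cls].items()},
                **{k: t.cap for k, t in CFG.positive[cls].items()}}
        for name, pts in res.component_points.items():
            if name != "sweeteners":
                assert 0 <= pts <= caps[name]
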