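"""Seeded synthetic procurement data emulating a Norwegian county's
high-school canteen purchases.

Two layers are generated:

* a product list (~4,800 items over 14 food groups) with per-100 g/100 ml
  nutrient content drawn from per-group distributions, plus a three-category
  guideline classification assigned from a latent "nutritional quality"
  score so that category and Nutri-Score correlate by construction, and
* per-school purchase ledgers (default 10 schools, half having received
  dietary guidance) in which value is allocated so that each school's
  recommended-category value share and A/B value share follow a planted
  linear relation — giving regression-recovery tests a known truth.

Every quantity the downstream pipeline recomputes (per-school value shares,
uncovered value) is also tallied at generation time with integer NOK
arithmetic and recorded in a truth sidecar, so pipeline-vs-truth equality
is exact, not approximate.

The default configuration mirrors the study conditions of the county audit
this package emulates: 4,790 products, a 53/33/14 category mix, 10 schools
(5 guided), ≈2.5% of purchase value not covered by the Nutri-Score, and an
A/B-vs-recommended slope of 0.94.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import scoring
from .agreement import letter_band

#: per-group generation parameters.  Masses are lognormal (median, sigma of
#: log) truncated to [0, 100] g; energy is normal (mean, sd) in kJ, floored
#: at 0; fvl is (probability of a nonzero value, beta a, beta b).
#: Beverages are per 100 ml, everything else per 100 g.
GROUP_NUTRIENTS: dict[str, dict] = {
    "Fruits and vegetables": dict(w=1335, energy=(250, 150), sugars=(5, 0.8),
                                  satfat=(0.1, 0.8), salt=(0.08, 1.2),
                                  protein=(1.5, 0.6), fiber=(2.5, 0.5),
                                  fvl=(0.95, 8, 1.5)),
    "Grains": dict(w=112, energy=(1500, 200), sugars=(2, 0.7), satfat=(0.4, 0.7),
                   salt=(0.3, 1.0), protein=(10, 0.3), fiber=(7, 0.4),
                   fvl=(0.05, 2, 5)),
    "Bread": dict(w=297, energy=(1100, 150), sugars=(3, 0.6), satfat=(0.5, 0.7),
                  salt=(1.0, 0.3), protein=(9, 0.25), fiber=(5, 0.45),
                  fvl=(0.02, 2, 5)),
    "Pasta and rice": dict(w=111, energy=(1500, 150), sugars=(1.5, 0.6),
                           satfat=(0.3, 0.7), salt=(0.03, 1.5),
                           protein=(11, 0.25), fiber=(3, 0.5), fvl=(0.02, 2, 5)),
    "Red meat": dict(w=460, energy=(900, 250), sugars=(0.7, 0.8), satfat=(4, 0.6),
                     salt=(1.5, 0.5), protein=(17, 0.2), fiber=(0.3, 0.8),
                     fvl=(0.02, 2, 5)),
    "White meat": dict(w=152, energy=(700, 200), sugars=(0.5, 0.8),
                       satfat=(1.5, 0.6), salt=(1.2, 0.5), protein=(18, 0.15),
                       fiber=(0.3, 0.8), fvl=(0.02, 2, 5)),
    "Fish and seafood": dict(w=218, energy=(700, 250), sugars=(1, 0.8),
                             satfat=(1.5, 0.7), salt=(1.3, 0.6),
                             protein=(16, 0.2), fiber=(0.2, 0.8), fvl=(0.03, 2, 5)),
    "Ready meals": dict(w=313, energy=(700, 250), sugars=(2.5, 0.7),
                        satfat=(2, 0.8), salt=(1.0, 0.5), protein=(6, 0.5),
                        fiber=(1.8, 0.6), fvl=(0.30, 2, 3)),
    "Sauces and dressings": dict(w=332, energy=(800, 400), sugars=(6, 0.9),
                                 satfat=(2, 1.0), salt=(1.8, 0.6),
                                 protein=(1.5, 0.7), fiber=(0.8, 0.8),
                                 fvl=(0.30, 2, 3)),
    "Dairy products and eggs": dict(w=387, energy=(700, 300), sugars=(5, 0.6),
                                    satfat=(5, 0.8), salt=(0.8, 0.7),
                                    protein=(8, 0.4), fiber=(0.1, 0.8),
                                    fvl=(0.01, 2, 5)),
    "Fats": dict(w=128, energy=(3000, 400), sugars=(0.3, 0.8), salt=(0.4, 1.0),
                 protein=(0.3, 0.8), fiber=(0.1, 0.8), fvl=(0.02, 2, 5),
                 total_fat=(80, 15), sat_ratio=(2, 4)),
    "Nuts": dict(w=73, energy=(2500, 300), sugars=(3, 0.8), salt=(0.4, 1.2),
                 protein=(20, 0.2), fiber=(7, 0.3), fvl=(0.05, 2, 5),
                 total_fat=(50, 10), sat_ratio=(1.5, 8)),
    "Snacks": dict(w=456, energy=(2000, 300), sugars=(35, 0.5), satfat=(8, 0.6),
                   salt=(1.0, 0.8), protein=(5, 0.5), fiber=(2, 0.6),
                   fvl=(0.05, 2, 5)),
    "Beverages": dict(w=416, energy=(160, 90), sugars=(6, 0.6), satfat=(0.2, 0.8),
                      salt=(0.05, 1.0), protein=(1.5, 0.8), fiber=(0.2, 0.8),
                      fvl=(0.30, 3, 2)),
}

SUPPLIERS = ("TINE", "Bama", "Servicegrossisten")


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic cohort; the defaults ARE the emulated study
    conditions and are not meant to be tuned per run."""

    seed: int
    n_products: int = 4790
    #: marginal guideline-category mix (recommended, limited, not recommended)
    category_mix: tuple[float, float, float] = (0.53, 0.33, 0.14)
    #: correlation knob in [0, 1] between latent nutritional quality and the
    #: assigned category; 0 = categories independent of nutrients
    quality_coupling: float = 0.85
    #: probability a product is outside Nutri-Score coverage (spices, ...)
    p_uncovered: float = 0.04
    n_schools: int = 10
    n_guided: int = 5
    #: mean recommended-category value share (%) by guidance status
    guided_recommended_center: float = 62.0
    unguided_recommended_center: float = 44.0
    recommended_sd: float = 9.0
    #: mean not-recommended value share (%) by guidance status
    guided_notrec_center: float = 7.0
    unguided_notrec_center: float = 20.0
    notrec_sd: float = 5.0
    #: planted linear relation: AB share = intercept + slope * recommended share
    planted_slope: float = 0.94
    planted_intercept: float = -6.0
    planted_noise_sd: float = 3.0
    #: per-school total purchase value, lognormal around the mean (NOK/quarter)
    school_value_mean: float = 163_000.0
    school_value_sigma: float = 0.35
    #: distinct products purchased per school
    products_per_school: int = 330
    #: fraction of a school's value spent on uncovered products
    uncovered_value_frac: tuple[float, float] = (0.01, 0.04)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise GeneratorError("seed is mandatory")
        if abs(sum(self.category_mix) - 1.0) > 1e-9:
            raise GeneratorError("category_mix must sum to 1")
        if not (0 <= self.quality_coupling <= 1):
            raise GeneratorError("quality_coupling must lie in [0, 1]")
        if self.n_schools < 1:
            raise GeneratorError("n_schools must be >= 1")
        if not (0 <= self.n_guided <= self.n_schools):
            raise GeneratorError("n_guided must lie in [0, n_schools]")
        if self.n_products < 1:
            raise GeneratorError("n_products must be >= 1")


def _lognormal(rng, median: float, sigma: float, n: int,
               cap: float = 100.0) -> np.ndarray:
    return np.minimum(rng.lognormal(np.log(median), sigma, n), cap)


def generate_products(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the product list: nutrients per group, flags, roles, and a
    guideline category coupled to latent nutritional quality.

    Fully reproducible per seed; every row satisfies the nutrient-profile
    invariants of the scoring engine.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_products
    groups = list(GROUP_NUTRIENTS)
    weights = np.array([GROUP_NUTRIENTS[g]["w"] for g in groups], dtype=float)
    weights /= weights.sum()
    group = rng.choice(groups, size=n, p=weights)

    cols = {c: np.zeros(n) for c in ("energy_kj", "sugars_g", "saturated_fat_g",
                                     "salt_g", "protein_g", "fiber_g",
                                     "fvl_percent")}
    total_fat = np.full(n, np.nan)
    is_water = np.zeros(n, dtype=bool)
    sweetener = np.zeros(n, dtype=bool)

    for g in groups:
        m = group == g
        k = int(m.sum())
        if k == 0:
            continue
        p = GROUP_NUTRIENTS[g]
        cols["energy_kj"][m] = np.maximum(rng.normal(*p["energy"], k), 0.0)
        cols["sugars_g"][m] = _lognormal(rng, *p["sugars"], k)
        cols["salt_g"][m] = _lognormal(rng, *p["salt"], k)
        cols["protein_g"][m] = _lognormal(rng, *p["protein"], k)
        cols["fiber_g"][m] = _lognormal(rng, *p["fiber"], k)
        if "total_fat" in p:
            tf = np.clip(rng.normal(*p["total_fat"], k), 1.0, 100.0)
            ratio = rng.beta(*p["sat_ratio"], k)
            total_fat[m] = tf
            cols["saturated_fat_g"][m] = tf * ratio
        else:
            cols["saturated_fat_g"][m] = _lognormal(rng, *p["satfat"], k)
        p_nz, a, b = p["fvl"]
        nz = rng.random(k) < p_nz
        fvl = np.zeros(k)
        fvl[nz] = 100.0 * rng.beta(a, b, int(nz.sum()))
        cols["fvl_percent"][m] = fvl
        if g == "Beverages":
            water = rng.random(k) < 0.08
            is_water[m] = water
            sweetener[m] = (rng.random(k) < 0.20) & ~water
            # water carries nothing
            for c in cols:
                cols[c][m] = np.where(water, 0.0, cols[c][m])

    # latent quality: low energy/sugar/sat-fat/salt, high fiber/FVL is good
    def z(x):
        return (x - x.mean()) / (x.std() or 1.0)

    quality = (-z(cols["energy_kj"]) - z(cols["sugars_g"])
               - z(cols["saturated_fat_g"]) - z(cols["salt_g"])
               + 0.5 * (z(cols["fiber_g"]) + z(cols["fvl_percent"])))
    # rank-inverse-normal so the latent score is standard normal regardless
    # of the nutrient marginals
    ranks = pd.Series(quality).rank(method="first").to_numpy()
    q_norm = norm.ppf(ranks / (n + 1))
    kappa = config.quality_coupling
    s = kappa * q_norm + np.sqrt(max(0.0, 1 - kappa**2)) * rng.standard_normal(n)
    rec, lim, notrec = config.category_mix
    upper = norm.ppf(1 - rec)      # above -> recommended
    lower = norm.ppf(notrec)       # below -> not recommended
    category = np.where(s >= upper, "recommended",
                        np.where(s < lower, "not_recommended", "limited"))

    roles = np.array([None] * n, dtype=object)
    portion = np.full(n, np.nan)
    u = rng.random(n)
    m = group == "Sauces and dressings"
    roles[m & (u < 0.30)] = "small-quantity ingredient"
    roles[m & (u >= 0.30) & (u < 0.40)] = "oil-based dressing"
    m = group == "Fish and seafood"
    roles[m & (u < 0.20)] = "bread topping"
    m = group == "Dairy products and eggs"
    roles[m & (u < 0.15)] = "bread topping"
    m = (group == "Beverages") & ~is_water
    juice = m & (u < 0.25)
    roles[juice] = "juice"
    portion[juice] = rng.choice([200.0, 250.0, 330.0, 500.0], int(juice.sum()))

    df = pd.DataFrame({
        "product_id": [f"P{i:05d}" for i in range(1, n + 1)],
        "supplier": rng.choice(SUPPLIERS, n),
        "food_group": group,
        "matvalget_category": category,
        "energy_kj": cols["energy_kj"].round(1),
        "sugars_g": cols["sugars_g"].round(2),
        "saturated_fat_g": cols["saturated_fat_g"].round(2),
        "total_fat_g": total_fat.round(2),
        "salt_g": cols["salt_g"].round(2),
        "protein_g": cols["protein_g"].round(2),
        "fiber_g": cols["fiber_g"].round(2),
        "fvl_percent": cols["fvl_percent"].round(1),
        "has_nonnutritive_sweeteners": sweetener,
        "is_water": is_water,
        "is_red_meat": group == "Red meat",
        "is_cheese": (group == "Dairy products and eggs") & (rng.random(n) < 0.35),
        "discontinued": False,
        "covered_by_nutriscore": rng.random(n) >= config.p_uncovered,
        "role": roles,
        "portion_ml": portion,
        "whole_grain": np.isin(group, ["Bread", "Grains", "Pasta and rice"])
        & (rng.random(n) < 0.5),
    })
    return df


def _allocate(rng, total: int, k: int) -> np.ndarray:
    """Split an integer NOK total over k lines (Dirichlet weights, integer
    rounding with the remainder on the first line)."""
    w = rng.dirichlet(np.ones(k) * 2.0)
    parts = np.floor(w * total).astype(int)
    parts[0] += total - parts.sum()
    return parts


def generate_ledger(scored_products: pd.DataFrame, config: GeneratorConfig
                    ) -> tuple[pd.DataFrame, dict]:
    """Generate per-school purchase ledgers plus the truth sidecar.

    ``scored_products`` must already carry ``nutri_letter`` / ``algorithm``
    columns (the generator allocates value by category x letter band to
    realize the planted share targets).  All line values are integer NOK, so
    the sidecar's integer tallies equal any order of downstream summation
    exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    covered = scored_products[scored_products["covered_by_nutriscore"].astype(bool)]
    uncovered = scored_products[~scored_products["covered_by_nutriscore"].astype(bool)]
    if covered.empty:
        raise GeneratorError("no covered products to purchase")

    bands = covered["nutri_letter"].map(letter_band)
    ab = bands == "A-B"
    pools: dict[tuple[str, bool], pd.Index] = {}
    f_cat: dict[str, float] = {}
    for cat in ("recommended", "limited", "not_recommended"):
        m = covered["matvalget_category"] == cat
        f_cat[cat] = float(ab[m].mean()) if m.any() else 0.0
        pools[(cat, True)] = covered.index[m & ab]
        pools[(cat, False)] = covered.index[m & ~ab]

    lines = []
    school_truth = {}
    for i in range(config.n_schools):
        school = f"S{i + 1:02d}"
        guided = i < config.n_guided
        x = float(np.clip(rng.normal(
            config.guided_recommended_center if guided
            else config.unguided_recommended_center,
            config.recommended_sd), 15, 85))
        znr = float(np.clip(rng.normal(
            config.guided_notrec_center if guided else config.unguided_notrec_center,
            config.notrec_sd), 1, 95 - x))
        y = float(np.clip(config.planted_intercept + config.planted_slope * x
                          + rng.normal(0, config.planted_noise_sd), 2, 95))
        cat_frac = {"recommended": x / 100, "not_recommended": znr / 100,
                    "limited": 1 - x / 100 - znr / 100}
        # scale within-category A/B fractions so the overall A/B share hits y
        y0 = sum(cat_frac[c] * f_cat[c] for c in cat_frac)
        t = (y / 100) / y0 if y0 > 0 else 0.0
        g_cat = {c: float(np.clip(t * f_cat[c], 0.0, 1.0)) for c in cat_frac}

        total = int(round(rng.lognormal(np.log(config.school_value_mean),
                                        config.school_value_sigma)))
        unc_frac = rng.uniform(*config.uncovered_value_frac) if len(uncovered) else 0.0
        unc_value = int(round(total * unc_frac))
        cov_value = total - unc_value

        n_lines = max(4, int(rng.poisson(config.products_per_school)))
        cell_fracs = {}
        for c in cat_frac:
            for is_ab in (True, False):
                frac = cat_frac[c] * (g_cat[c] if is_ab else 1 - g_cat[c])
                if frac > 0 and len(pools[(c, is_ab)]) > 0:
                    cell_fracs[(c, is_ab)] = frac
        # renormalise over populated cells; empty cells forfeit their value
        norm_total = sum(cell_fracs.values())
        cell_values = {cell: int(round(cov_value * f / norm_total))
                       for cell, f in cell_fracs.items()}

        for cell, v in cell_values.items():
            if v <= 0:
                continue
            pool = pools[cell]
            k = min(len(pool), max(1, int(round(n_lines * cell_fracs[cell]))))
            chosen = rng.choice(pool.to_numpy(), size=k, replace=False)
            for pid_idx, val in zip(chosen, _allocate(rng, v, k)):
                if val > 0:
                    lines.append((school, scored_products.at[pid_idx, "product_id"],
                                  int(val)))
        if unc_value > 0:
            k = min(len(uncovered), max(1, unc_value // 2000 + 1))
            chosen = rng.choice(uncovered.index.to_numpy(), size=k, replace=False)
            for pid_idx, val in zip(chosen, _allocate(rng, unc_value, k)):
                if val > 0:
                    lines.append((school, scored_products.at[pid_idx, "product_id"],
                                  int(val)))
        school_truth[school] = {"received_guidance": guided,
                                "target_recommended_share": x,
                                "target_ab_share": y,
                                "target_not_recommended_share": znr}

    ledger = pd.DataFrame(lines, columns=["school_id", "product_id", "value_nok"])
    ledger["units"] = rng.integers(1, 60, len(ledger))
    ledger["amount"] = (ledger["units"] * rng.uniform(0.2, 5.0, len(ledger))).round(2)
    ledger = ledger[["school_id", "product_id", "units", "amount", "value_nok"]]
    ledger["value_nok"] = ledger["value_nok"].astype(float)

    # exact integer bookkeeping of the realized shares (the truth sidecar)
    prod = scored_products.set_index("product_id")
    for school, df in ledger.groupby("school_id"):
        tallies = {"covered": 0, "total": 0, "ab": 0, "unfavorable": 0,
                   "recommended": 0, "limited": 0, "not_recommended": 0}
        for pid, val in zip(df["product_id"], df["value_nok"]):
            v = int(val)
            tallies["total"] += v
            if not bool(prod.at[pid, "covered_by_nutriscore"]):
                continue
            tallies["covered"] += v
            letter = prod.at[pid, "nutri_letter"]
            is_bev = prod.at[pid, "algorithm"] == "beverage"
            if letter in ("A", "B"):
                tallies["ab"] += v
            if letter == "E" or (is_bev and letter in ("C", "D")):
                tallies["unfavorable"] += v
            tallies[prod.at[pid, "matvalget_category"]] += v
        cov = tallies["covered"]
        school_truth[school].update({
            "total_value": float(tallies["total"]),
            "covered_value": float(cov),
            "uncovered_pct": 100.0 * (tallies["total"] - cov) / tallies["total"],
            "share_ab": 100.0 * tallies["ab"] / cov,
            "share_unfavorable": 100.0 * tallies["unfavorable"] / cov,
            "share_recommended": 100.0 * tallies["recommended"] / cov,
            "share_limited": 100.0 * tallies["limited"] / cov,
            "share_not_recommended": 100.0 * tallies["not_recommended"] / cov,
        })

    truth = {"config": {"seed": config.seed,
                        "planted_slope": config.planted_slope,
                        "planted_intercept": config.planted_intercept,
                        "n_schools": config.n_schools,
                        "n_guided": config.n_guided},
             "schools": school_truth}
    return ledger, truth


def guidance_map(truth: dict) -> dict[str, bool]:
    return {s: t["received_guidance"] for s, t in truth["schools"].items()}


def simulate_study(config: GeneratorConfig
                   ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Products (already scored), ledger and truth sidecar in one call."""
    products = generate_products(config)
    scored = scoring.score_products_frame(products)
    ledger, truth = generate_ledger(scored, config)
    return scored, ledger, truth
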