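"""Purchase-value shares per school, the share-vs-share regression, and
procurement goal evaluation.

Shares are percentages of each school's *covered* purchase value (value on
products the Nutri-Score cannot cover is reported separately, never folded
into a letter class).  The unfavorable class is letter E for foods and
letters C–E for beverages, because beverages that the guidelines advise
against cluster in C.  The Viken County guideline goal (>=70% of value on
recommended foods, <=8% on not-recommended) maps onto a Nutri-Score goal of
>=65% on A/B and <=15% unfavorable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm


class GoalsError(ValueError):
    pass


def unfavorable_band(letter: str, is_beverage: bool) -> bool:
    """True for letter E, or letters C-E when the product is a beverage."""
    if letter not in ("A", "B", "C", "D", "E"):
        raise GoalsError(f"unknown Nutri-Score letter {letter!r}")
    if letter == "E":
        return True
    return is_beverage and letter in ("C", "D")


@dataclass(frozen=True)
class GoalSet:
    """Value-share goals: at least ``min_favorable``% on the favorable class,
    at most ``max_unfavorable``% on the unfavorable class, on either the
    guideline-category basis or the Nutri-Score basis."""

    min_favorable: float
    max_unfavorable: float
    basis: str  # "guideline" | "nutriscore"

    def __post_init__(self) -> None:
        for v in (self.min_favorable, self.max_unfavorable):
            if not (0 <= v <= 100):
                raise GoalsError("goal thresholds must lie in [0, 100]")
        if self.basis not in ("guideline", "nutriscore"):
            raise GoalsError(f"unknown goal basis {self.basis!r}")


#: Viken County's guideline-basis goal and its Nutri-Score-basis counterpart
GUIDELINE_GOALS = GoalSet(min_favorable=70.0, max_unfavorable=8.0, basis="guideline")
NUTRISCORE_GOALS = GoalSet(min_favorable=65.0, max_unfavorable=15.0, basis="nutriscore")

SHARE_COLUMNS = ("school_id", "total_value", "covered_value", "uncovered_pct",
                 "share_ab", "share_mid", "share_unfavorable",
                 "share_recommended", "share_limited", "share_not_recommended",
                 "received_guidance")


def value_shares(purchases: pd.DataFrame, scored_products: pd.DataFrame,
                 guidance: dict[str, bool] | None = None) -> pd.DataFrame:
    """Per-school purchase-value shares by Nutri-Score class and guideline
    category.

    ``scored_products`` must carry ``product_id``, ``nutri_letter``,
    ``algorithm``, ``matvalget_category`` and ``covered_by_nutriscore``.
    A school with zero covered value cannot have shares and raises.
    """
    prod = scored_products.set_index("product_id")
    joined = purchases.merge(
        prod[["nutri_letter", "algorithm", "matvalget_category",
              "covered_by_nutriscore"]],
        left_on="product_id", right_index=True, how="left")
    known = joined["nutri_letter"].notna()
    covered = known & joined["covered_by_nutriscore"].fillna(False).astype(bool)
    joined["covered"] = covered
    is_bev = joined["algorithm"] == "beverage"
    joined["unfavorable"] = [
        unfavorable_band(l, b) if c else False
        for l, b, c in zip(joined["nutri_letter"].fillna("E"), is_bev, covered)]
    joined["ab"] = covered & joined["nutri_letter"].isin(["A", "B"])

    rows = []
    for school, df in joined.groupby("school_id", sort=True):
        total = float(df["value_nok"].sum())
        cov = float(df.loc[df["covered"], "value_nok"].sum())
        if cov == 0:
            raise GoalsError(f"school {school!r} has zero covered purchase value")
        cdf = df[df["covered"]]

        def share(mask) -> float:
            return 100.0 * float(cdf.loc[mask, "value_nok"].sum()) / cov

        share_ab = share(cdf["ab"])
        share_unf = share(cdf["unfavorable"])
        rows.append({
            "school_id": school,
            "total_value": total,
            "covered_value": cov,
            "uncovered_pct": 100.0 * (total - cov) / total if total else 0.0,
            "share_ab": share_ab,
            "share_mid": 100.0 - share_ab - share_unf,
            "share_unfavorable": share_unf,
            "share_recommended": share(cdf["matvalget_category"] == "recommended"),
            "share_limited": share(cdf["matvalget_category"] == "limited"),
            "share_not_recommended": share(cdf["matvalget_category"] == "not_recommended"),
            "received_guidance": bool((guidance or {}).get(school, False)),
        })
    return pd.DataFrame(rows, columns=list(SHARE_COLUMNS))


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    p_value: float
    stderr: float
    n: int
    r_squared: float


def fit_share_regression(x, y) -> RegressionFit:
    """OLS of y on x (both in percent), e.g. A/B value share on
    recommended-category value share across schools."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise GoalsError("x and y must have equal length")
    if x.size < 3:
        raise GoalsError(f"need at least 3 schools for a regression, got {x.size}")
    if np.ptp(x) == 0:
        raise GoalsError("zero variance in x: slope is not identified")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(slope=float(model.params[1]),
                         intercept=float(model.params[0]),
                         p_value=float(model.pvalues[1]),
                         stderr=float(model.bse[1]),
                         n=int(x.size),
                         r_squared=float(model.rsquared))


def predict_favorable_goal(fit: RegressionFit, guideline_goal: float) -> float:
    """Translate a guideline-basis goal into the Nutri-Score basis via the
    fitted line (plain inverse prediction: y at x = goal)."""
    return fit.intercept + fit.slope * guideline_goal


def goal_evaluation(shares: pd.DataFrame, goals: GoalSet) -> pd.DataFrame:
    """Pass/fail per school against a goal set, with margins.

    Bounds are inclusive: a share exactly at the threshold passes.
    Guideline-basis goals read the category shares, Nutri-Score-basis goals
    the letter shares; mixing bases is refused.
    """
    if goals.basis == "nutriscore":
        fav, unf = "share_ab", "share_unfavorable"
    else:
        fav, unf = "share_recommended", "share_not_recommended"
    for col in (fav, unf):
        if col not in shares.columns or shares[col].isna().any():
            raise GoalsError(f"shares are missing {col!r} for basis {goals.basis!r}")
    out = shares[["school_id", fav, unf]].copy()
    out = out.rename(columns={fav: "favorable_share", unf: "unfavorable_share"})
    out["favorable_pass"] = out["favorable_share"] >= goals.min_favorable
    out["favorable_margin"] = out["favorable_share"] - goals.min_favorable
    out["unfavorable_pass"] = out["unfavorable_share"] <= goals.max_unfavorable
    out["unfavorable_margin"] = goals.max_unfavorable - out["unfavorable_share"]
    out["both_pass"] = out["favorable_pass"] & out["unfavorable_pass"]
    return out
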