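"""Agreement between Nutri-Score letters and the three-category school-meal
guideline classification (the Matvalget expert classification used as a
guideline proxy in Norwegian county school procurement audits).

Agreement pairs: (recommended, A/B), (limited, C/D), (not recommended, E).
Disagreement pairs: (recommended, D/E) and (limited or not recommended, A/B).
The remaining four letter/category pairs are neutral.

Cross tables use the letter bands A-B / C / D-E.  The D-E band cannot
distinguish D from E, so agreement for the "limited" category is not
band-resolvable: agreement totals are always computed from product-level
letters, while disagreement (which only involves whole bands) can be read
off the banded table as well.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .scoring import LETTERS


class MatvalgetCategory(enum.Enum):
    RECOMMENDED = "recommended"
    LIMITED = "limited"
    NOT_RECOMMENDED = "not_recommended"


CATEGORIES = tuple(c.value for c in MatvalgetCategory)


class AgreementStatus(enum.Enum):
    AGREE = "agree"
    DISAGREE = "disagree"
    NEUTRAL = "neutral"


BANDS = ("A-B", "C", "D-E")

_AGREE = {("recommended", "A"), ("recommended", "B"),
          ("limited", "C"), ("limited", "D"),
          ("not_recommended", "E")}
_DISAGREE = {("recommended", "D"), ("recommended", "E"),
             ("limited", "A"), ("limited", "B"),
             ("not_recommended", "A"), ("not_recommended", "B")}


def letter_band(letter: str) -> str:
    """Collapse a letter to the reporting bands A-B / C / D-E."""
    if letter in ("A", "B"):
        return "A-B"
    if letter == "C":
        return "C"
    if letter in ("D", "E"):
        return "D-E"
    raise ValueError(f"unknown Nutri-Score letter {letter!r}")


def agreement_status(category: MatvalgetCategory | str, letter: str) -> AgreementStatus:
    """Classify one (guideline category, letter) pair."""
    cat = MatvalgetCategory(category).value
    if letter not in LETTERS:
        raise ValueError(f"unknown Nutri-Score letter {letter!r}")
    if (cat, letter) in _AGREE:
        return AgreementStatus.AGREE
    if (cat, letter) in _DISAGREE:
        return AgreementStatus.DISAGREE
    return AgreementStatus.NEUTRAL


@dataclass(frozen=True)
class CrossTable:
    """Letter-band x guideline-category counts for one grouping label."""

    label: str
    counts: pd.DataFrame  # index BANDS, columns CATEGORIES, integer cells

    def __post_init__(self) -> None:
        if list(self.counts.index) != list(BANDS) or \
                list(self.counts.columns) != list(CATEGORIES):
            raise ValueError("cross table must be indexed by bands x categories")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("cross table counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def column_percentages(self) -> pd.DataFrame:
        """Percent of each category column falling in each band (full precision)."""
        col_totals = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * self.counts / col_totals
        return pct.fillna(0.0)

    def to_report_frame(self) -> pd.DataFrame:
        """Published-style layout: band rows, '% (N)' cells, integer-rounded."""
        pct = self.column_percentages()
        cells = {}
        for cat in CATEGORIES:
            cells[cat] = [f"{round(pct.loc[b, cat]):.0f} ({self.counts.loc[b, cat]:,})"
                          for b in BANDS]
        return pd.DataFrame(cells, index=BANDS)


def build_cross_table(products: pd.DataFrame,
                      group_by_food_group: bool = False
                      ) -> CrossTable | dict[str, CrossTable]:
    """Tabulate letter-band x category counts, overall or per food group.

    ``products`` needs columns ``nutri_letter`` and ``matvalget_category``
    (plus ``food_group`` when grouping).  An empty input yields a valid
    all-zero table.
    """
    def one(label: str, df: pd.DataFrame) -> CrossTable:
        counts = pd.DataFrame(0, index=list(BANDS), columns=list(CATEGORIES))
        if len(df):
            bands = df["nutri_letter"].map(letter_band)
            cats = df["matvalget_category"].map(lambda c: MatvalgetCategory(c).value)
            tab = pd.crosstab(bands, cats)
            counts = counts.add(tab.reindex(index=BANDS, columns=CATEGORIES,
                                            fill_value=0), fill_value=0).astype(int)
        return CrossTable(label=label, counts=counts.astype(int))

    if not group_by_food_group:
        return one("Overall", products)
    return {g: one(g, df) for g, df in products.groupby("food_group", sort=True)}


def disagreement_summary(table: CrossTable) -> tuple[int, float]:
    """Disagreement count and share of the table total.

    Disagreement is band-resolvable: (recommended x D-E) + (limited x A-B)
    + (not recommended x A-B).
    """
    c = table.counts
    count = int(c.loc["D-E", "recommended"]
                + c.loc["A-B", "limited"]
                + c.loc["A-B", "not_recommended"])
    total = table.total
    share = 100.0 * count / total if total else 0.0
    return count, share


def product_level_summary(products: pd.DataFrame) -> dict[str, float]:
    """Agreement/disagreement/neutral counts and shares from product-level letters.

    This is the authoritative route for agreement (the banded table cannot
    split D from E inside the "limited" category).
    """
    statuses = [agreement_status(c, l) for c, l in
                zip(products["matvalget_category"], products["nutri_letter"])]
    n = len(statuses)
    counts = {s: sum(1 for x in statuses if x is s) for s in AgreementStatus}
    out = {"n": n}
    for s in AgreementStatus:
        out[f"{s.value}_n"] = counts[s]
        out[f"{s.value}_pct"] = 100.0 * counts[s] / n if n else 0.0
    return out


def category_mix(table: CrossTable) -> dict[str, float]:
    """Share of products in each guideline category (percent of table total)."""
    col = table.counts.sum(axis=0)
    total = table.total
    return {cat: (100.0 * int(col[cat]) / total if total else 0.0)
            for cat in CATEGORIES}


def points_distribution(products: pd.DataFrame) -> pd.DataFrame:
    """Five-number summaries of final Nutri-Score points per
    (guideline category, algorithm class) stratum; empty strata omitted.

    Quartiles use linear interpolation on the sorted scores.
    """
    rows = []
    for (cat, alg), df in products.groupby(["matvalget_category", "algorithm"]):
        scores = df["nutri_score"].to_numpy(dtype=float)
        if scores.size == 0:
            continue
        q1, med, q3 = np.quantile(scores, [0.25, 0.5, 0.75])
        rows.append({"matvalget_category": MatvalgetCategory(cat).value,
                     "algorithm": alg, "n": scores.size,
                     "min": scores.min(), "q1": q1, "median": med,
                     "q3": q3, "max": scores.max()})
    return pd.DataFrame(rows)


def load_published_crosstab() -> dict[str, CrossTable]:
    """Published Viken County cross-tabulation (2021–2023 procurements,
    n = 4,790), transcribed cell by cell; keyed by grouping label with
    'Overall' first.

    Note: the snacks x limited x D-E cell is transcribed as printed even
    though it is internally inconsistent with its row total.
    """
    path = resources.files("nutriprocure.data") / "viken_crosstab.csv"
    with resources.as_file(path) as p:
        raw = pd.read_csv(p)
    out = {}
    for label, df in raw.groupby("food_group", sort=False):
        counts = (df.set_index("band")[list(CATEGORIES)]
                  .reindex(BANDS).astype(int))
        counts.index.name = None
        out[label] = CrossTable(label=label, counts=counts)
    return out
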