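"""Reading and cleaning of product lists and school purchase ledgers.

The cleaning mirrors a county procurement audit: duplicate product numbers
are dropped first, then items the Nutri-Score does not cover (herbs,
spices, ...), then discontinued items, then everything not sourced from an
explicit supplier allowlist.  Every removal is tallied in a
:class:`CleaningReport` so input, removals and output always reconcile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

PRODUCT_REQUIRED_COLUMNS = (
    "product_id", "supplier", "food_group", "matvalget_category",
    "energy_kj", "sugars_g", "saturated_fat_g", "salt_g",
    "protein_g", "fiber_g",
)
PRODUCT_OPTIONAL_COLUMNS = (
    "total_fat_g", "fvl_percent", "has_nonnutritive_sweeteners", "is_water",
    "is_red_meat", "is_cheese", "discontinued", "covered_by_nutriscore",
    "role", "portion_ml", "whole_grain",
)
PURCHASE_REQUIRED_COLUMNS = ("school_id", "product_id", "units", "amount", "value_nok")


class PipelineError(ValueError):
    """Malformed input schema or configuration."""


@dataclass
class CleaningConfig:
    dedupe: bool = True
    drop_uncovered: bool = True
    drop_discontinued: bool = True
    supplier_allowlist: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.supplier_allowlist is not None and len(self.supplier_allowlist) == 0:
            raise PipelineError("supplier allowlist enabled but empty")


@dataclass
class CleaningReport:
    """Per-step removal tallies; initial - sum(removed) == final always holds."""

    initial: int
    duplicates: int = 0
    not_covered: int = 0
    discontinued: int = 0
    supplier_excluded: int = 0
    final: int = 0

    def removed(self) -> int:
        return (self.duplicates + self.not_covered
                + self.discontinued + self.supplier_excluded)

    def check(self) -> None:
        if self.initial - self.removed() != self.final:
            raise AssertionError("cleaning report does not conserve records")

    def as_dict(self) -> dict[str, int]:
        return {"initial": self.initial, "duplicates": self.duplicates,
                "not_covered": self.not_covered, "discontinued": self.discontinued,
                "supplier_excluded": self.supplier_excluded, "final": self.final}


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PipelineError(f"{what} file is missing mandatory column(s): "
                            + ", ".join(missing))


def read_products(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a product list CSV into typed records plus a rejects frame.

    Malformed rows (blank product id, negative nutrient amounts, unknown
    category) go to the rejects frame with a ``reject_reason`` column; they
    are never dropped silently.
    """
    df = pd.read_csv(path, dtype={"product_id": str, "supplier": str})
    _require_columns(df, PRODUCT_REQUIRED_COLUMNS, "products")
    for col in PRODUCT_OPTIONAL_COLUMNS:
        if col not in df.columns:
            if col in ("has_nonnutritive_sweeteners", "is_water", "is_red_meat",
                       "is_cheese", "discontinued", "whole_grain"):
                df[col] = False
            elif col == "covered_by_nutriscore":
                df[col] = True
            elif col == "fvl_percent":
                # conservative default: no unearned favorable points
                df[col] = 0.0
            else:
                df[col] = pd.NA
    reasons = pd.Series("", index=df.index)
    bad_id = df["product_id"].isna() | (df["product_id"].str.strip() == "")
    reasons[bad_id] += "empty product_id;"
    for col in ("energy_kj", "sugars_g", "saturated_fat_g", "salt_g",
                "protein_g", "fiber_g"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0)
        reasons[bad] += f"invalid {col};"
    known = {"recommended", "limited", "not_recommended"}
    bad_cat = ~df["matvalget_category"].isin(known)
    reasons[bad_cat] += "unknown matvalget_category;"
    rejects = df[reasons != ""].copy()
    rejects["reject_reason"] = reasons[reasons != ""]
    return df[reasons == ""].reset_index(drop=True), rejects.reset_index(drop=True)


def read_purchases(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a purchase ledger CSV; rows with negative or missing value are rejected."""
    df = pd.read_csv(path, dtype={"product_id": str, "school_id": str})
    _require_columns(df, PURCHASE_REQUIRED_COLUMNS, "purchases")
    value = pd.to_numeric(df["value_nok"], errors="coerce")
    bad = value.isna() | (value < 0)
    rejects = df[bad].copy()
    rejects["reject_reason"] = "invalid value_nok"
    kept = df[~bad].copy()
    kept["value_nok"] = value[~bad]
    return kept.reset_index(drop=True), rejects.reset_index(drop=True)


def clean_products(products: pd.DataFrame,
                   config: CleaningConfig = CleaningConfig()
                   ) -> tuple[pd.DataFrame, CleaningReport]:
    """Apply the audit cleaning steps in order:
    dedupe -> uncovered -> discontinued -> supplier filter.

    Deduplication keeps the first occurrence in input order, so the result
    is deterministic for a given file.  The returned report reconciles
    exactly; cleaning is idempotent.
    """
    report = CleaningReport(initial=len(products))
    df = products
    if config.dedupe:
        keep = ~df["product_id"].duplicated(keep="first")
        report.duplicates = int((~keep).sum())
        df = df[keep]
    if config.drop_uncovered:
        keep = df["covered_by_nutriscore"].astype(bool)
        report.not_covered = int((~keep).sum())
        df = df[keep]
    if config.drop_discontinued:
        keep = ~df["discontinued"].astype(bool)
        report.discontinued = int((~keep).sum())
        df = df[keep]
    if config.supplier_allowlist is not None:
        keep = df["supplier"].isin(config.supplier_allowlist)
        report.supplier_excluded = int((~keep).sum())
        df = df[keep]
    df = df.reset_index(drop=True)
    report.final = len(df)
    report.check()
    return df, report


def coverage_report(purchases: pd.DataFrame,
                    products: pd.DataFrame) -> tuple[int, float]:
    """Items (distinct products purchased) not scoreable, and their share of
    total purchase value.

    A purchased product is not scoreable when it is unknown to the product
    list or flagged as not covered by the Nutri-Score.  Uncovered value is
    kept in the total (reported, not discarded).
    """
    total_value = float(purchases["value_nok"].sum())
    if total_value == 0:
        raise PipelineError("total purchase value is zero; coverage share undefined")
    covered_ids = set(products.loc[products["covered_by_nutriscore"].astype(bool),
                                   "product_id"])
    uncovered_mask = ~purchases["product_id"].isin(covered_ids)
    n_items = int(purchases.loc[uncovered_mask, "product_id"].nunique())
    value_share = 100.0 * float(purchases.loc[uncovered_mask, "value_nok"].sum()) / total_value
    return n_items, value_share
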