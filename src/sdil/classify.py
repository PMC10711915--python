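"""Levy category assignment and small-manufacturer flagging.

The Soft Drinks Industry Levy is a two-tier tax on manufacturers of soft
drinks: drinks with >=8 g total sugar per 100 mL fall in the high tier, >=5 to
<8 g in the low tier, and <5 g drinks carry no levy (subdivided here into
>0-<5 g and exactly 0 g, with bottled water kept as its own category). Drinks
are exempt irrespective of sugar when they contain >75% milk, >1.2% alcohol by
volume (or are sold as alcohol replacements), are sold as powders, or are 100%
fruit juice with no added sugar. Producers selling under one million litres of
levy-liable drinks a year are also exempt; because no public register of such
producers exists, they are approximated from observed purchase volumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd

#: Mutually exclusive category labels, exhaustive over accepted products.
CATEGORY_LABELS = (
    "high_tier",
    "low_tier",
    "no_levy_low_sugar",
    "no_levy_zero_sugar",
    "bottled_water",
    "exempt_milk_based",
    "exempt_alcohol",
    "exempt_juice",
    "exempt_powder",
    "confectionery",
    "toiletries",
    "excluded",
)

#: Levy-liable tiers (drinks neither exempt nor considered separately).
LEVY_LIABLE_LABELS = ("high_tier", "low_tier", "no_levy_low_sugar", "no_levy_zero_sugar")

TOILETRIES_GROUPS = frozenset({"shampoo", "hair conditioner", "liquid soap"})
CONFECTIONERY_GROUPS = frozenset({"sugar confectionery", "chocolate confectionery"})
ALCOHOL_REPLACEMENT_GROUPS = frozenset({"alcohol replacement"})
#: Product groups excluded from all analyses (no usable data or out of scope).
EXCLUDED_GROUPS = frozenset({"infant formula", "medical drink", "skimmed milk"})

HIGH_TIER_THRESHOLD = 8.0  # g sugar / 100 mL
LOW_TIER_THRESHOLD = 5.0
MILK_EXEMPTION_PCT = 75.0
ABV_EXEMPTION_PCT = 1.2


class ClassificationError(ValueError):
    """A product that cannot be assigned to any levy category."""


@dataclass(frozen=True)
class ProductRecord:
    """One marketed product, with the composition fields that drive levy status.

    ``sugar_g_per_100ml`` is grams of total sugar per 100 mL for liquids and per
    100 g for solids/powders; it may be ``None`` for products where sugar is not
    recorded (e.g. toiletries, alcohol).
    """

    product_id: str
    description: str
    product_group: str
    sugar_g_per_100ml: Optional[float]
    milk_content_pct: float = 0.0
    abv_pct: float = 0.0
    physical_form: str = "liquid"  # liquid | powder | solid
    juice_pct: float = 0.0
    is_bottled_water: bool = False
    no_added_sugar: bool = False
    manufacturer_id: str = ""

    def __post_init__(self) -> None:
        for name in ("milk_content_pct", "abv_pct", "juice_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name} must be in [0, 100], got {v}")
        if self.sugar_g_per_100ml is not None and self.sugar_g_per_100ml < 0:
            raise ValueError("sugar_g_per_100ml must be >= 0")
        if self.physical_form not in ("liquid", "powder", "solid"):
            raise ValueError(f"unknown physical_form {self.physical_form!r}")


def assign_category(product: ProductRecord) -> str:
    """Assign a product to exactly one levy category.

    Precedence: excluded groups, then toiletries/confectionery by product
    group, then the exemptions (milk, alcohol, powder, 100% juice with no
    added sugar), then bottled water, then the sugar tiers. Tier boundaries
    are inclusive at the threshold (sugar of exactly 8.0 is high tier, exactly
    5.0 is low tier), matching the ``>=`` definitions.
    """
    group = product.product_group.strip().lower()
    if group in EXCLUDED_GROUPS:
        return "excluded"
    if group in TOILETRIES_GROUPS:
        return "toiletries"
    if group in CONFECTIONERY_GROUPS:
        return "confectionery"
    if product.milk_content_pct > MILK_EXEMPTION_PCT:
        return "exempt_milk_based"
    if product.abv_pct > ABV_EXEMPTION_PCT or group in ALCOHOL_REPLACEMENT_GROUPS:
        return "exempt_alcohol"
    if product.physical_form == "powder":
        return "exempt_powder"
    if product.juice_pct == 100.0 and product.no_added_sugar:
        return "exempt_juice"
    if product.is_bottled_water:
        return "bottled_water"
    sugar = product.sugar_g_per_100ml
    if sugar is None:
        raise ClassificationError(
            f"product {product.product_id!r} ({product.description!r}) is a drink "
            "with no sugar concentration and no exemption route"
        )
    if sugar >= HIGH_TIER_THRESHOLD:
        return "high_tier"
    if sugar >= LOW_TIER_THRESHOLD:
        return "low_tier"
    if sugar > 0.0:
        return "no_levy_low_sugar"
    return "no_levy_zero_sugar"


def classify_catalogue(products: pd.DataFrame) -> pd.Series:
    """Category label per product for a products table.

    ``products`` uses the delimited-file schema (one row per product, columns as
    :class:`ProductRecord` fields). Returns a Series indexed by ``product_id``.
    """
    labels = {}
    for row in products.itertuples(index=False):
        sugar = getattr(row, "sugar_g_per_100ml", None)
        if sugar is not None and pd.isna(sugar):
            sugar = None
        record = ProductRecord(
            product_id=str(row.product_id),
            description=str(getattr(row, "description", "")),
            product_group=str(row.product_group),
            sugar_g_per_100ml=sugar,
            milk_content_pct=float(getattr(row, "milk_content_pct", 0.0)),
            abv_pct=float(getattr(row, "abv_pct", 0.0)),
            physical_form=str(getattr(row, "physical_form", "liquid")),
            juice_pct=float(getattr(row, "juice_pct", 0.0)),
            is_bottled_water=bool(getattr(row, "is_bottled_water", False)),
            no_added_sugar=bool(getattr(row, "no_added_sugar", False)),
            manufacturer_id=str(getattr(row, "manufacturer_id", "")),
        )
        labels[record.product_id] = assign_category(record)
    return pd.Series(labels, name="category").rename_axis("product_id")


def small_manufacturer_flags(
    purchases: pd.DataFrame,
    products: pd.DataFrame,
    threshold_litres_per_year: float = 1_000_000.0,
    category_map: Optional[Mapping[str, str]] = None,
) -> pd.Series:
    """Flag manufacturers whose mean annual levy-liable volume is below threshold.

    Levy-liable volume (mL) is summed per manufacturer per calendar year over
    the span of ``purchases``, the per-year mean is taken, and a manufacturer is
    flagged small when that mean (in litres) is strictly below
    ``threshold_litres_per_year``. Manufacturers present in the catalogue with
    no recorded levy-liable purchases are flagged small.
    """
    if threshold_litres_per_year <= 0:
        raise ValueError("threshold must be > 0")
    if len(purchases) == 0:
        raise ValueError("empty purchase set")
    cats = pd.Series(category_map) if category_map is not None else classify_catalogue(products)
    prod = products.set_index(products["product_id"].astype(str))
    liable_products = cats[cats.isin(LEVY_LIABLE_LABELS)].index

    events = purchases.copy()
    events["product_id"] = events["product_id"].astype(str)
    events = events[events["product_id"].isin(liable_products)]
    events["manufacturer_id"] = events["product_id"].map(prod["manufacturer_id"].astype(str))
    events["year"] = pd.to_datetime(events["week_start_date"]).dt.year

    yearly = events.groupby(["manufacturer_id", "year"])["quantity"].sum()
    years = sorted(pd.to_datetime(purchases["week_start_date"]).dt.year.unique())
    # Mean over all calendar years in the span (zero-volume years count).
    mean_ml = yearly.unstack("year").reindex(columns=years).fillna(0.0).mean(axis=1)

    all_manufacturers = pd.Index(sorted(products["manufacturer_id"].astype(str).unique()))
    mean_litres = (mean_ml / 1000.0).reindex(all_manufacturers).fillna(0.0)
    flags = mean_litres < threshold_litres_per_year
    flags.name = "is_small_manufacturer"
    flags.index.name = "manufacturer_id"
    return flags


def read_products(path) -> pd.DataFrame:
    """Read a products delimited file, normalising optional columns."""
    df = pd.read_csv(path)
    if "sugar_g_per_100ml" in df:
        df["sugar_g_per_100ml"] = pd.to_numeric(df["sugar_g_per_100ml"], errors="coerce")
    for col in ("is_bottled_water", "no_added_sugar"):
        if col in df:
            df[col] = df[col].astype(bool)
    return df


def write_category_map(labels: pd.Series, path) -> None:
    labels.rename("category").rename_axis("product_id").to_csv(path)
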