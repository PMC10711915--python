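"""Household filtering and weekly weighted aggregation of purchase events.

The outcome the models consume is the weighted mean volume (mL) or sugar mass
(g) purchased per household per week in one category. Panel membership per week
comes from the weights table: a household-week present there contributes zero
to a category it bought nothing from, so the mean correctly dilutes over
non-purchasers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

MEASURES = ("volume", "sugar_mass")


@dataclass
class WeeklySeries:
    """Ordered weekly per-household means for one category and measure."""

    label: str
    measure: str
    weeks: pd.DatetimeIndex
    values: np.ndarray
    n_households: np.ndarray
    unit: str = "mL"

    def __post_init__(self) -> None:
        self.weeks = pd.DatetimeIndex(self.weeks)
        self.values = np.asarray(self.values, dtype=float)
        self.n_households = np.asarray(self.n_households)
        if self.measure not in MEASURES:
            raise ValueError(f"measure must be one of {MEASURES}")
        if len(self.weeks) != len(self.values) or len(self.weeks) != len(self.n_households):
            raise ValueError("weeks, values and n_households must align")
        if len(self.weeks) > 1:
            gaps = np.diff(self.weeks.to_numpy()).astype("timedelta64[D]").astype(int)
            if (gaps != 7).any():
                raise ValueError("weeks must be strictly increasing with 7-day spacing")
        if not np.isfinite(self.values).all():
            raise ValueError("series values must be finite")

    def __len__(self) -> int:
        return len(self.weeks)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.weeks, name=self.label)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "week_start_date": self.weeks.date,
                "value": self.values,
                "n_households": self.n_households,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def filter_households(
    events: pd.DataFrame,
    min_weekly_purchases: int = 6,
    min_weekly_spend: float = 0.0,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Drop household-weeks recording too few purchases or too little spend.

    The purchase-count rule mirrors the panel operator's exclusion of
    household-weeks with fewer than six recorded purchases; the spend minimum
    is undisclosed in the source data, so it defaults to 0. Returns the
    retained events and an exclusion log (household_id, week_start_date,
    n_purchases, spend).
    """
    if min_weekly_purchases < 0:
        raise ValueError("min_weekly_purchases must be >= 0")
    if len(events) == 0 or (min_weekly_purchases == 0 and min_weekly_spend <= 0):
        return events, events.iloc[0:0][["household_id", "week_start_date"]].copy()

    grp = events.groupby(["household_id", "week_start_date"], sort=False)
    counts = grp.size().rename("n_purchases")
    spend = (
        grp["spend"].sum().rename("spend")
        if "spend" in events.columns
        else pd.Series(np.inf, index=counts.index, name="spend")
    )
    log = pd.concat([counts, spend], axis=1)
    bad = log[(log["n_purchases"] < min_weekly_purchases) | (log["spend"] < min_weekly_spend)]

    key = pd.MultiIndex.from_frame(events[["household_id", "week_start_date"]])
    retained = events[~key.isin(bad.index)]
    return retained, bad.reset_index()


def weekly_weighted_mean(
    events: pd.DataFrame,
    category_map: Mapping[str, str] | pd.Series,
    weights: pd.DataFrame,
    category_label: str,
    measure: str = "volume",
    sugar_concentration: Optional[Mapping[str, float] | pd.Series] = None,
    unit: str = "mL",
) -> WeeklySeries:
    """Weighted mean outcome per household per week for one category.

    Per week, each in-panel household's total quantity (or sugar mass,
    ``sum(quantity * sugar_g_per_100 / 100)``) over the category's products is
    computed, households without purchases contribute zero, and the weighted
    mean ``sum(w_h * x_h) / sum(w_h)`` is taken over the panel.
    """
    cat = pd.Series(category_map)
    if category_label not in set(cat.values):
        raise ValueError(f"unknown category label {category_label!r}")
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}")

    products_in_cat = cat[cat == category_label].index
    ev = events[events["product_id"].isin(products_in_cat)].copy()

    if measure == "sugar_mass":
        if sugar_concentration is None:
            raise ValueError("sugar_mass requires per-product sugar concentrations")
        conc = pd.Series(sugar_concentration).reindex(products_in_cat)
        if conc.isna().all():
            raise ValueError(f"category {category_label!r} has no sugar data")
        ev["x"] = ev["quantity"] * ev["product_id"].map(conc).to_numpy() / 100.0
        if ev["x"].isna().any():
            raise ValueError(f"missing sugar concentration for products in {category_label!r}")
        unit = "g"
    else:
        ev["x"] = ev["quantity"]
        if "unit" in ev.columns and ev["unit"].nunique() == 1 and len(ev):
            unit = str(ev["unit"].iloc[0])

    hh_week = ev.groupby(["household_id", "week_start_date"], sort=False)["x"].sum()

    panel = weights[["household_id", "week_start_date", "weight"]].copy()
    if (panel["weight"] <= 0).any():
        raise ValueError("panel weights must be > 0")
    idx = pd.MultiIndex.from_frame(panel[["household_id", "week_start_date"]])
    panel["x"] = hh_week.reindex(idx).fillna(0.0).to_numpy()
    panel["wx"] = panel["weight"] * panel["x"]

    by_week = panel.groupby("week_start_date").agg(
        wx=("wx", "sum"), w=("weight", "sum"), n=("household_id", "size")
    )
    by_week = by_week.sort_index()
    if (by_week["n"] == 0).any() or (by_week["w"] <= 0).any():
        raise ValueError("weeks with an empty panel cannot be aggregated")
    return WeeklySeries(
        label=category_label,
        measure=measure,
        weeks=pd.DatetimeIndex(by_week.index),
        values=(by_week["wx"] / by_week["w"]).to_numpy(),
        n_households=by_week["n"].to_numpy(),
        unit=unit,
    )


def combine_categories(series: Sequence[WeeklySeries], new_label: str) -> WeeklySeries:
    """Week-wise sum of several category series sharing one grid and measure.

    Used for the combined groupings (all soft drinks; levy-liable only; sugar
    bands irrespective of levy eligibility). Powder grams add to liquid
    millilitres numerically; the combined unit is reported as mL-equivalent
    when inputs mix units.
    """
    if not series:
        raise ValueError("no series to combine")
    first = series[0]
    values = np.zeros(len(first))
    units = set()
    for s in series:
        if s.measure != first.measure:
            raise ValueError("cannot combine series with different measures")
        if len(s) != len(first) or (s.weeks != first.weeks).any():
            raise ValueError("cannot combine series on mismatched week grids")
        values = values + s.values
        units.add(s.unit)
    unit = units.pop() if len(units) == 1 else "mL-equivalent"
    return WeeklySeries(
        label=new_label,
        measure=first.measure,
        weeks=first.weeks,
        values=values,
        n_households=first.n_households.copy(),
        unit=unit,
    )


def read_series(path, label: str, measure: str = "volume", unit: str = "mL") -> WeeklySeries:
    df = pd.read_csv(path, parse_dates=["week_start_date"])
    return WeeklySeries(
        label=label,
        measure=measure,
        weeks=pd.DatetimeIndex(df["week_start_date"]),
        values=df["value"].to_numpy(),
        n_households=df["n_households"].to_numpy(),
        unit=unit,
    )
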