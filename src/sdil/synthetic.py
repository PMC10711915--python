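"""Synthetic household purchase panel with known intervention effects.

The real evaluation used a proprietary market-research purchase panel, so every
downstream stage here is exercised against a seeded generator with a closed-form
ground truth instead. Each levy category follows an additive weekly process per
household:

    E[y_ct] = baseline + trend*t + seasonal sinusoid + Christmas/Easter uplifts
              + level & slope changes switched on at the announcement week
              + level & slope changes switched on at the implementation week

Realised household values add a time-constant household effect (between-
household heterogeneity) and a week-level AR(1) disturbance common to all
households, so the aggregated weekly series is exactly a segmented-regression
mean plus AR(1) noise — the structure the analysis model assumes, which makes
parameter recovery a fair test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .classify import ProductRecord
from .weeks import Calendar, WEEKS_PER_YEAR, christmas_indicator, easter_indicator, default_calendar


class DegenerateCounterfactualError(ValueError):
    """The counterfactual path is non-positive at the requested week."""


@dataclass(frozen=True)
class CategoryProcessSpec:
    """Data-generating process for one levy category's weekly outcome.

    Units are mL per household per week for drinks and g per household per week
    for powders and confectionery. ``noise_sd`` scales the common week-level
    AR(1) disturbance; ``household_sd`` the time-constant household effects.
    """

    category_label: str
    baseline_level: float
    weekly_trend: float = 0.0
    seasonal_amplitude: float = 0.0
    christmas_uplift: float = 0.0
    easter_uplift: float = 0.0
    announcement_level_change: float = 0.0
    announcement_slope_change: float = 0.0
    implementation_level_change: float = 0.0
    implementation_slope_change: float = 0.0
    noise_sd: float = 0.0
    household_sd: float = 0.0
    ar1_coefficient: float = 0.0
    market_loading: float = 1.0  # exposure to the market-wide weekly shock
    sugar_g_per_100: Optional[float] = None  # shared by the category's products
    unit: str = "mL"

    def __post_init__(self) -> None:
        if self.baseline_level < 0:
            raise ValueError("baseline_level must be >= 0")
        if self.noise_sd < 0 or self.household_sd < 0:
            raise ValueError("noise scales must be >= 0")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise ValueError("ar1_coefficient must be in [0, 1)")
        if self.easter_uplift != 0.0 and self.category_label != "confectionery":
            raise ValueError("easter_uplift is only allowed for confectionery")


@dataclass(frozen=True)
class ManufacturerSpec:
    """A manufacturer with a purchase-share weight and a size class."""

    manufacturer_id: str
    share_weight: float
    size_class: str  # "small" | "large"


@dataclass
class SimulationConfig:
    """Full configuration of a synthetic panel run."""

    n_households: int = 1000
    calendar: Calendar = field(default_factory=default_calendar)
    category_specs: Dict[str, CategoryProcessSpec] = field(default_factory=dict)
    control_category: str = "toiletries"
    weight_sigma: float = 0.5  # lognormal sigma of household weights (mean 1)
    #: Market-wide AR(1) weekly shock shared by all categories (scaled by each
    #: category's market_loading). Zero by default; positive values make the
    #: control category informative about common purchasing disturbances.
    market_noise_sd: float = 0.0
    market_ar1: float = 0.5
    manufacturers: Tuple[ManufacturerSpec, ...] = (
        ManufacturerSpec("M_BIG1", 0.45, "large"),
        ManufacturerSpec("M_BIG2", 0.30, "large"),
        ManufacturerSpec("M_MID", 0.18, "large"),
        ManufacturerSpec("M_SMALL1", 0.05, "small"),
        ManufacturerSpec("M_SMALL2", 0.02, "small"),
    )
    products_per_category: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.category_specs and self.control_category not in self.category_specs:
            raise ValueError(
                f"control category {self.control_category!r} missing from category_specs"
            )


def expected_path(spec: CategoryProcessSpec, calendar: Calendar) -> np.ndarray:
    """Deterministic expected weekly per-household outcome for one category."""
    t = np.arange(calendar.n_weeks, dtype=float)
    weeks = calendar.week_starts
    t_a, t_i = calendar.announcement_week, calendar.implementation_week
    a = (t >= t_a).astype(float)
    i = (t >= t_i).astype(float)
    path = (
        spec.baseline_level
        + spec.weekly_trend * t
        + spec.seasonal_amplitude * np.sin(2.0 * np.pi * t / WEEKS_PER_YEAR)
        + spec.christmas_uplift * christmas_indicator(weeks)
        + spec.easter_uplift * easter_indicator(weeks)
        + spec.announcement_level_change * a
        + spec.announcement_slope_change * (t - t_a) * a
        + spec.implementation_level_change * i
        + spec.implementation_slope_change * (t - t_i) * i
    )
    return path


def _intervention_terms(spec: CategoryProcessSpec, calendar: Calendar, week: int, analysis_id: int) -> float:
    """Sum of the intervention terms counted by the given analysis at ``week``."""
    t_a, t_i = calendar.announcement_week, calendar.implementation_week
    ann = 0.0
    if week >= t_a:
        ann = spec.announcement_level_change + spec.announcement_slope_change * (week - t_a)
    imp = 0.0
    if week >= t_i:
        imp = spec.implementation_level_change + spec.implementation_slope_change * (week - t_i)
    if analysis_id == 1:
        return ann
    if analysis_id == 2:
        return imp
    if analysis_id == 3:
        return ann + imp
    raise ValueError("analysis_id must be 1, 2 or 3")


def true_effect(
    config: SimulationConfig,
    category: str,
    analysis_id: int,
    week: int,
    measure: str = "volume",
) -> Tuple[float, float]:
    """Closed-form (absolute change, relative change %) versus counterfactual.

    ``analysis_id`` selects which interruption terms count as the intervention:
    1 = announcement only, 2 = implementation only, 3 = both combined. The
    counterfactual is the expected path with those terms removed. For
    ``measure='sugar_mass'`` the volume effect is scaled by the category's
    sugar concentration (all products of a category share one concentration).
    """
    cal = config.calendar
    if not 0 <= week < cal.n_weeks:
        raise ValueError(f"week {week} outside simulated span")
    spec = config.category_specs[category]
    path = expected_path(spec, cal)[week]
    effect = _intervention_terms(spec, cal, week, analysis_id)
    counterfactual = path - effect
    if measure == "sugar_mass":
        if spec.sugar_g_per_100 is None:
            raise ValueError(f"category {category!r} has no sugar concentration")
        scale = spec.sugar_g_per_100 / 100.0
        effect *= scale
        counterfactual *= scale
    elif measure != "volume":
        raise ValueError(f"unknown measure {measure!r}")
    if counterfactual <= 0:
        raise DegenerateCounterfactualError(
            f"counterfactual for {category!r} at week {week} is {counterfactual:.3f} <= 0"
        )
    return effect, 100.0 * effect / counterfactual


# ---------------------------------------------------------------------------
# Catalogue
# ---------------------------------------------------------------------------

#: Composition template per category: fields that force the intended label.
_CATEGORY_COMPOSITION = {
    "high_tier": dict(product_group="carbonates", sugar=10.9, form="liquid"),
    "low_tier": dict(product_group="carbonates", sugar=6.5, form="liquid"),
    "no_levy_low_sugar": dict(product_group="carbonates", sugar=2.2, form="liquid"),
    "no_levy_zero_sugar": dict(product_group="carbonates", sugar=0.0, form="liquid"),
    "bottled_water": dict(product_group="bottled water", sugar=0.0, form="liquid", water=True),
    "exempt_milk_based": dict(product_group="milk drinks", sugar=4.8, form="liquid", milk=88.0),
    "exempt_alcohol": dict(product_group="beer", sugar=None, form="liquid", abv=4.5),
    "exempt_juice": dict(product_group="fruit juice", sugar=9.8, form="liquid", juice=100.0, nas=True),
    "exempt_powder": dict(product_group="powdered drink", sugar=22.0, form="powder"),
    "confectionery": dict(product_group="chocolate confectionery", sugar=56.0, form="solid"),
    "toiletries": dict(product_group="shampoo", sugar=None, form="liquid"),
}


def simulate_catalogue(config: SimulationConfig) -> pd.DataFrame:
    """Products table covering every configured category.

    Within a category all products share the category's sugar concentration
    (``CategoryProcessSpec.sugar_g_per_100`` when set, else the template value),
    so sugar series have the same closed-form ground truth as volume series.
    Manufacturers are assigned round-robin from the configured list, which spans
    both small and large size classes.
    """
    if not config.category_specs:
        raise ValueError("config has no category_specs")
    if config.control_category not in config.category_specs:
        raise ValueError("config has no control category")
    rng = np.random.default_rng(config.seed)
    rows = []
    manufacturers = list(config.manufacturers)
    k = 0
    for label, spec in config.category_specs.items():
        if label not in _CATEGORY_COMPOSITION:
            raise ValueError(f"unknown category label {label!r}")
        tmpl = _CATEGORY_COMPOSITION[label]
        sugar = spec.sugar_g_per_100 if spec.sugar_g_per_100 is not None else tmpl["sugar"]
        for j in range(config.products_per_category):
            manu = manufacturers[k % len(manufacturers)]
            k += 1
            rows.append(
                dict(
                    product_id=f"P{len(rows) + 1:04d}",
                    description=f"{label.replace('_', ' ')} product {j + 1}",
                    product_group=tmpl["product_group"],
                    sugar_g_per_100ml=sugar,
                    milk_content_pct=tmpl.get("milk", 0.0),
                    abv_pct=tmpl.get("abv", 0.0),
                    physical_form=tmpl["form"],
                    juice_pct=tmpl.get("juice", 0.0),
                    is_bottled_water=tmpl.get("water", False),
                    no_added_sugar=tmpl.get("nas", False),
                    manufacturer_id=manu.manufacturer_id,
                    unit_price=float(np.round(rng.uniform(0.0008, 0.004), 6)),
                    intended_category=label,
                )
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Panel
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Exact expected series and closed-form effects for a simulated panel."""

    config: SimulationConfig
    expected: pd.DataFrame  # weeks x categories, expected per-household outcome

    def expected_series(self, category: str) -> pd.Series:
        return self.expected[category]

    def effect(self, category: str, analysis_id: int, week: int, measure: str = "volume"):
        return true_effect(self.config, category, analysis_id, week, measure)


def _ar1(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) disturbance with marginal standard deviation ``sd``."""
    if sd == 0.0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sd)
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    shocks = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        e[t] = rho * e[t - 1] + shocks[t - 1]
    return e


def simulate_panel(
    config: SimulationConfig,
    catalogue: Optional[pd.DataFrame] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate purchase events and household weights for the configured panel.

    Returns ``(events, weights, ground_truth)``. Events carry one row per
    household x week x category, with the household's weekly category total
    assigned to one randomly chosen product of that category (weighted by
    manufacturer share), so category sums are exact. Household weights are
    lognormal with mean 1, constant over the span, written per household-week.

    Raises if any category's expected weekly value is negative anywhere in the
    span: such configs would demand truncation, which biases recovery tests.
    """
    if not config.category_specs:
        raise ValueError("config has no category_specs")
    cal = config.calendar
    weeks = cal.week_starts
    n_h, n_w = config.n_households, cal.n_weeks
    if catalogue is None:
        catalogue = simulate_catalogue(config)

    expected = {}
    for label, spec in config.category_specs.items():
        path = expected_path(spec, cal)
        if (path < 0).any():
            w = int(np.argmax(path < 0))
            raise ValueError(
                f"expected value for {label!r} is negative at week {w} "
                f"({path[w]:.2f}); config invalid over this span"
            )
        expected[label] = path
    truth = GroundTruth(config=config, expected=pd.DataFrame(expected, index=weeks))

    rng = np.random.default_rng(config.seed)
    household_ids = np.array([f"H{i + 1:05d}" for i in range(n_h)])
    # Lognormal weights with mean 1; mu = -sigma^2/2.
    sigma = config.weight_sigma
    w_h = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_h) if sigma > 0 else np.ones(n_h)

    manu_share = {m.manufacturer_id: m.share_weight for m in config.manufacturers}
    price = catalogue.set_index("product_id")["unit_price"] if "unit_price" in catalogue else None
    m_t = _ar1(rng, n_w, config.market_ar1, config.market_noise_sd)

    frames = []
    for label, spec in config.category_specs.items():
        b_h = rng.normal(0.0, spec.household_sd, size=n_h) if spec.household_sd > 0 else np.zeros(n_h)
        u_t = _ar1(rng, n_w, spec.ar1_coefficient, spec.noise_sd) + spec.market_loading * m_t
        y = expected[label][None, :] + b_h[:, None] + u_t[None, :]
        np.clip(y, 0.0, None, out=y)  # events cannot record negative quantities

        cat_products = catalogue[catalogue["intended_category"] == label]
        if len(cat_products) == 0:
            raise ValueError(f"catalogue has no products for {label!r}")
        probs = np.array(
            [manu_share.get(m, 1.0) for m in cat_products["manufacturer_id"]], dtype=float
        )
        probs /= probs.sum()
        choice = rng.choice(cat_products["product_id"].to_numpy(), size=(n_h, n_w), p=probs)

        frames.append(
            pd.DataFrame(
                {
                    "household_id": np.repeat(household_ids, n_w),
                    "week_start_date": np.tile(weeks.to_numpy(), n_h),
                    "product_id": choice.ravel(),
                    "quantity": y.ravel(),
                    "unit": spec.unit,
                }
            )
        )
    events = pd.concat(frames, ignore_index=True)
    if price is not None:
        events["spend"] = events["quantity"] * events["product_id"].map(price).to_numpy()
    events = events.sort_values(["household_id", "week_start_date", "product_id"], kind="stable")
    events = events.reset_index(drop=True)

    weights = pd.DataFrame(
        {
            "household_id": np.repeat(household_ids, n_w),
            "week_start_date": np.tile(weeks.to_numpy(), n_h),
            "weight": np.repeat(w_h, n_w),
        }
    )
    return events, weights, truth


# ---------------------------------------------------------------------------
# Default study conditions
# ---------------------------------------------------------------------------


def default_category_specs() -> Dict[str, CategoryProcessSpec]:
    """Default per-category processes for the full synthetic study.

    Baselines, trends and holiday uplifts are anchored to the published
    pre-announcement weekly means; interruption effects carry the published
    signs with whole-intervention magnitudes of comparable size. Sugar
    concentrations reproduce each category's sugar-to-volume ratio.
    """
    return {
        "high_tier": CategoryProcessSpec(
            "high_tier", baseline_level=990.0, weekly_trend=-2.0, seasonal_amplitude=45.0,
            christmas_uplift=70.0, announcement_slope_change=0.33,
            implementation_level_change=-120.0, implementation_slope_change=-1.0,
            noise_sd=30.0, household_sd=180.0, ar1_coefficient=0.5, sugar_g_per_100=11.1,
        ),
        "low_tier": CategoryProcessSpec(
            "low_tier", baseline_level=150.0, weekly_trend=0.1, seasonal_amplitude=12.0,
            christmas_uplift=15.0, announcement_level_change=-10.0,
            announcement_slope_change=-0.55, implementation_level_change=-20.0,
            implementation_slope_change=-0.6, noise_sd=9.0, household_sd=30.0,
            ar1_coefficient=0.5, sugar_g_per_100=6.5,
        ),
        "no_levy_low_sugar": CategoryProcessSpec(
            "no_levy_low_sugar", baseline_level=774.0, weekly_trend=0.2, seasonal_amplitude=50.0,
            christmas_uplift=30.0, announcement_level_change=20.0, announcement_slope_change=0.8,
            implementation_level_change=120.0, implementation_slope_change=2.5,
            noise_sd=25.0, household_sd=150.0, ar1_coefficient=0.5, sugar_g_per_100=1.55,
        ),
        "no_levy_zero_sugar": CategoryProcessSpec(
            "no_levy_zero_sugar", baseline_level=1000.0, weekly_trend=0.5, seasonal_amplitude=60.0,
            christmas_uplift=40.0, announcement_level_change=30.0, announcement_slope_change=0.55,
            implementation_level_change=100.0, implementation_slope_change=1.5,
            noise_sd=30.0, household_sd=200.0, ar1_coefficient=0.5, sugar_g_per_100=0.0,
        ),
        "bottled_water": CategoryProcessSpec(
            "bottled_water", baseline_level=560.0, weekly_trend=0.6, seasonal_amplitude=70.0,
            announcement_level_change=-10.0, announcement_slope_change=-0.2,
            implementation_level_change=-60.0, implementation_slope_change=-0.8,
            noise_sd=25.0, household_sd=120.0, ar1_coefficient=0.5, sugar_g_per_100=0.0,
        ),
        "exempt_alcohol": CategoryProcessSpec(
            "exempt_alcohol", baseline_level=1850.0, weekly_trend=0.05, seasonal_amplitude=60.0,
            christmas_uplift=250.0, announcement_slope_change=-0.1,
            implementation_level_change=-50.0, implementation_slope_change=-0.7,
            noise_sd=80.0, household_sd=400.0, ar1_coefficient=0.5,
        ),
        "exempt_milk_based": CategoryProcessSpec(
            "exempt_milk_based", baseline_level=3540.0, weekly_trend=0.0, seasonal_amplitude=30.0,
            christmas_uplift=60.0, announcement_level_change=-150.0,
            announcement_slope_change=-0.2, implementation_level_change=100.0,
            implementation_slope_change=-0.5, noise_sd=35.0, household_sd=700.0,
            ar1_coefficient=0.5, sugar_g_per_100=4.85,
        ),
        "exempt_juice": CategoryProcessSpec(
            "exempt_juice", baseline_level=518.0, weekly_trend=-0.05, seasonal_amplitude=20.0,
            christmas_uplift=20.0, announcement_level_change=5.0,
            noise_sd=10.0, household_sd=100.0, ar1_coefficient=0.5, sugar_g_per_100=9.8,
        ),
        "exempt_powder": CategoryProcessSpec(
            "exempt_powder", baseline_level=97.0, weekly_trend=-0.05, seasonal_amplitude=8.0,
            christmas_uplift=10.0, announcement_level_change=-5.0,
            announcement_slope_change=-0.02, implementation_level_change=10.0,
            noise_sd=3.0, household_sd=20.0, ar1_coefficient=0.5,
            sugar_g_per_100=22.0, unit="g",
        ),
        "confectionery": CategoryProcessSpec(
            "confectionery", baseline_level=300.0, weekly_trend=0.02, seasonal_amplitude=15.0,
            christmas_uplift=80.0, easter_uplift=40.0, implementation_level_change=30.0,
            noise_sd=20.0, household_sd=60.0, ar1_coefficient=0.5,
            sugar_g_per_100=56.0, unit="g",
        ),
        "toiletries": CategoryProcessSpec(
            "toiletries", baseline_level=123.0, weekly_trend=-0.02, seasonal_amplitude=2.0,
            christmas_uplift=3.0, noise_sd=3.0, household_sd=25.0, ar1_coefficient=0.5,
        ),
    }


def default_config(n_households: int = 1000, seed: int = 0) -> SimulationConfig:
    """The package's default synthetic study conditions."""
    return SimulationConfig(
        n_households=n_households,
        calendar=default_calendar(),
        category_specs=default_category_specs(),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------


def write_panel(out_dir, events: pd.DataFrame, catalogue: pd.DataFrame, weights: pd.DataFrame,
                truth: GroundTruth) -> None:
    """Write purchases/products/weights CSVs and a ground-truth JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ev = events.copy()
    ev["week_start_date"] = pd.to_datetime(ev["week_start_date"]).dt.date
    ev.to_csv(out / "purchases.csv", index=False)
    catalogue.to_csv(out / "products.csv", index=False)
    wt = weights.copy()
    wt["week_start_date"] = pd.to_datetime(wt["week_start_date"]).dt.date
    wt.to_csv(out / "weights.csv", index=False)

    cal = truth.config.calendar
    sidecar = {
        "calendar": {
            "start_date": cal.start_date.isoformat(),
            "n_weeks": cal.n_weeks,
            "announcement_week": cal.announcement_week,
            "implementation_week": cal.implementation_week,
        },
        "n_households": truth.config.n_households,
        "seed": truth.config.seed,
        "category_specs": {k: asdict(v) for k, v in truth.config.category_specs.items()},
        "expected_series": {
            k: [round(float(v), 6) for v in truth.expected[k]] for k in truth.expected
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))
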