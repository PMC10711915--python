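"""Run the full levy evaluation: all categories x measures x three analyses,
the combined-category secondary analysis, and both sensitivity analyses.

Failures are isolated per category/measure/analysis so that one degenerate
series does not sink a thirty-model run; every configured combination appears
either in the effects table or in the failure log.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import aggregate, classify, cits, effects, synthetic
from .weeks import Calendar, default_calendar

log = logging.getLogger(__name__)

#: Categories with no usable sugar series (no sugar, or sugar unrecorded).
SUGARLESS_CATEGORIES = frozenset(
    {"exempt_alcohol", "no_levy_zero_sugar", "bottled_water", "toiletries"}
)

#: Combined groupings for the secondary analysis. Bottled water counts inside
#: "all soft drinks" but outside the levy-liable subtotal.
COMBINED_GROUPS: Dict[str, Tuple[str, ...]] = {
    "all_soft_drinks": (
        "high_tier", "low_tier", "no_levy_low_sugar", "no_levy_zero_sugar",
        "bottled_water", "exempt_milk_based", "exempt_juice", "exempt_powder",
    ),
    "levy_liable": ("high_tier", "low_tier", "no_levy_low_sugar", "no_levy_zero_sugar"),
}

#: Sugar-band groupings irrespective of levy eligibility (g sugar / 100 units).
SUGAR_BANDS = {
    "band_ge8": lambda s: s >= 8.0,
    "band_5_to_8": lambda s: (s >= 5.0) & (s < 8.0),
    "band_lt5": lambda s: s < 5.0,
}


@dataclass
class StudyConfig:
    """Everything needed to run the study on one panel."""

    calendar: Calendar = field(default_factory=default_calendar)
    control_category: str = "toiletries"
    uncontrolled: bool = False
    categories: Optional[Sequence[str]] = None  # default: all found in the catalogue
    min_weekly_purchases: int = 6
    min_weekly_spend: float = 0.0
    error_model: str = "hac"
    n_harmonics: int = 2
    easter_categories: frozenset = frozenset({"confectionery"})
    #: Small-manufacturer exclusion thresholds, litres of levy-liable volume
    #: per year observed in the panel (1M and 0.5M at full panel scale).
    small_manufacturer_thresholds: Tuple[float, ...] = (1_000_000.0, 500_000.0)
    analyses: Tuple[int, ...] = (1, 2, 3)
    seed: int = 0


@dataclass
class StudyInputs:
    """A loaded panel: events, products, weights, and the category map."""

    events: pd.DataFrame
    products: pd.DataFrame
    weights: pd.DataFrame
    category_map: pd.Series
    sugar_concentration: pd.Series

    @classmethod
    def from_frames(cls, events, products, weights) -> "StudyInputs":
        cat = classify.classify_catalogue(products)
        conc = products.set_index(products["product_id"].astype(str))["sugar_g_per_100ml"]
        return cls(events, products, weights, cat, conc)

    @classmethod
    def from_dir(cls, panel_dir) -> "StudyInputs":
        panel_dir = Path(panel_dir)
        events = pd.read_csv(panel_dir / "purchases.csv", parse_dates=["week_start_date"])
        products = classify.read_products(panel_dir / "products.csv")
        weights = pd.read_csv(panel_dir / "weights.csv", parse_dates=["week_start_date"])
        return cls.from_frames(events, products, weights)


def _apply_household_filter(inputs: StudyInputs, config: StudyConfig) -> StudyInputs:
    retained, excluded = aggregate.filter_households(
        inputs.events, config.min_weekly_purchases, config.min_weekly_spend
    )
    weights = inputs.weights
    if len(excluded):
        # excluded household-weeks leave the panel entirely, mirroring the
        # panel operator's practice (weights then re-balance the remainder)
        key = pd.MultiIndex.from_frame(weights[["household_id", "week_start_date"]])
        bad = pd.MultiIndex.from_frame(excluded[["household_id", "week_start_date"]])
        weights = weights[~key.isin(bad)]
    return StudyInputs(retained, inputs.products, weights, inputs.category_map, inputs.sugar_concentration)


def _series_for(inputs: StudyInputs, label: str, measure: str) -> aggregate.WeeklySeries:
    unit = "g" if measure == "sugar_mass" else "mL"
    return aggregate.weekly_weighted_mean(
        inputs.events,
        inputs.category_map,
        inputs.weights,
        label,
        measure,
        sugar_concentration=inputs.sugar_concentration,
        unit=unit,
    )


def _control_series(inputs: StudyInputs, config: StudyConfig) -> Optional[aggregate.WeeklySeries]:
    if config.uncontrolled:
        return None
    if config.control_category not in set(inputs.category_map.values):
        raise ValueError(
            f"control category {config.control_category!r} not present in the catalogue"
        )
    return _series_for(inputs, config.control_category, "volume")


def fit_one(
    series: aggregate.WeeklySeries,
    config: StudyConfig,
    analysis_id: int,
    control: Optional[aggregate.WeeklySeries],
    easter: bool = False,
) -> cits.CITSFit:
    cal = config.calendar
    spec = cits.InterruptionSpec(
        announcement_week=cal.announcement_week,
        implementation_week=cal.implementation_week,
        analysis_id=analysis_id,
    )
    design = cits.build_design(
        series.weeks, spec, control_series=control,
        n_harmonics=config.n_harmonics, easter=easter,
    )
    return cits.fit(design, series, error_model=config.error_model)


def _run_categories(
    inputs: StudyInputs,
    config: StudyConfig,
    labels: Sequence[str],
    series_builder,
) -> Tuple[pd.DataFrame, List[dict]]:
    """Shared loop: fit every label x measure x analysis, isolating failures."""
    control = _control_series(inputs, config)
    estimates, failures = [], []
    for label in labels:
        for measure in ("volume", "sugar_mass"):
            if measure == "sugar_mass" and label in SUGARLESS_CATEGORIES:
                continue
            try:
                series = series_builder(label, measure)
            except Exception as exc:  # degenerate series must not sink the run
                for analysis_id in config.analyses:
                    failures.append(
                        dict(category=label, measure=measure, analysis=analysis_id, error=str(exc))
                    )
                log.warning("series %s/%s failed: %s", label, measure, exc)
                continue
            for analysis_id in config.analyses:
                try:
                    fit_result = fit_one(
                        series, config, analysis_id, control,
                        easter=label in config.easter_categories,
                    )
                    estimates.append(effects.estimate_effect(fit_result))
                except Exception as exc:
                    failures.append(
                        dict(category=label, measure=measure, analysis=analysis_id, error=str(exc))
                    )
                    log.warning("fit %s/%s analysis %d failed: %s", label, measure, analysis_id, exc)
    return effects.effects_table(estimates), failures


def run_primary(inputs: StudyInputs, config: StudyConfig) -> Tuple[pd.DataFrame, List[dict]]:
    """One effect estimate per category x measure x analysis.

    Sugar models are skipped for alcohol (sugar unrecorded) and for zero-sugar
    categories; the control category is not itself an outcome.
    """
    filtered = _apply_household_filter(inputs, config)
    labels = config.categories
    if labels is None:
        labels = [
            c for c in classify.CATEGORY_LABELS
            if c in set(filtered.category_map.values)
            and c not in ("excluded", config.control_category)
        ]
    return _run_categories(filtered, config, labels, lambda l, m: _series_for(filtered, l, m))


def run_secondary_combined(inputs: StudyInputs, config: StudyConfig) -> Tuple[pd.DataFrame, List[dict]]:
    """Combined groupings: all soft drinks, levy-liable only, and sugar bands."""
    filtered = _apply_household_filter(inputs, config)
    present = set(filtered.category_map.values)

    def builder(label: str, measure: str):
        if label in COMBINED_GROUPS:
            members = [c for c in COMBINED_GROUPS[label] if c in present]
            if measure == "sugar_mass":
                members = [c for c in members if c not in SUGARLESS_CATEGORIES]
            series = [_series_for(filtered, c, measure) for c in members]
            return aggregate.combine_categories(series, label)
        # sugar bands: re-map soft-drink products by concentration
        predicate = SUGAR_BANDS[label]
        soft = filtered.category_map[
            ~filtered.category_map.isin(["exempt_alcohol", "toiletries", "confectionery", "excluded"])
        ]
        conc = filtered.sugar_concentration.reindex(soft.index).fillna(0.0)
        band_map = pd.Series(
            np.where(predicate(conc.to_numpy()), label, "other"), index=soft.index
        )
        return aggregate.weekly_weighted_mean(
            filtered.events, band_map, filtered.weights, label, measure,
            sugar_concentration=filtered.sugar_concentration,
            unit="g" if measure == "sugar_mass" else "mL-equivalent",
        )

    labels = list(COMBINED_GROUPS) + list(SUGAR_BANDS)
    return _run_categories(filtered, config, labels, builder)


def run_sensitivity(inputs: StudyInputs, config: StudyConfig) -> Dict[str, Tuple[pd.DataFrame, List[dict]]]:
    """Small-manufacturer exclusion at each threshold, plus the uncontrolled model."""
    out: Dict[str, Tuple[pd.DataFrame, List[dict]]] = {}
    for threshold in config.small_manufacturer_thresholds:
        if threshold == 0:
            out[f"exclude_small_{threshold:g}"] = run_primary(inputs, config)
            continue
        flags = classify.small_manufacturer_flags(
            inputs.events, inputs.products, threshold, category_map=inputs.category_map
        )
        small = set(flags[flags].index)
        prod = inputs.products.set_index(inputs.products["product_id"].astype(str))
        # the small-producer exemption covers levy-liable drinks only, so the
        # exclusion drops those products and leaves exempt categories intact
        liable = inputs.category_map.isin(classify.LEVY_LIABLE_LABELS)
        from_small = prod["manufacturer_id"].astype(str).isin(small) & liable.reindex(
            prod.index
        ).fillna(False)
        keep_products = set(prod.index[~from_small])
        events = inputs.events[inputs.events["product_id"].astype(str).isin(keep_products)]
        trimmed = StudyInputs(
            events, inputs.products, inputs.weights, inputs.category_map, inputs.sugar_concentration
        )
        out[f"exclude_small_{threshold:g}"] = run_primary(trimmed, config)
    from dataclasses import replace as _replace
    out["no_control"] = run_primary(inputs, _replace(config, uncontrolled=True))
    return out


def concordance(primary: pd.DataFrame, other: pd.DataFrame) -> pd.DataFrame:
    """Sign-and-significance agreement between two effects tables.

    'Significant' means the 95% CI for the absolute change excludes zero — the
    same rule that bolds entries in the report tables. A pure function of the
    two tables.
    """
    key = ["category", "measure", "analysis"]
    merged = primary.merge(other, on=key, suffixes=("_primary", "_other"))
    merged["same_sign"] = np.sign(merged["absolute_change_primary"]) == np.sign(
        merged["absolute_change_other"]
    )
    merged["same_significance"] = merged["significant_primary"] == merged["significant_other"]
    return merged[key + ["absolute_change_primary", "absolute_change_other",
                         "same_sign", "same_significance"]]


# ---------------------------------------------------------------------------
# Run-to-disk driver
# ---------------------------------------------------------------------------


def run_study(
    inputs: StudyInputs,
    config: StudyConfig,
    out_dir,
    sensitivity: bool = True,
    combined: bool = True,
) -> Dict[str, pd.DataFrame]:
    """Run the configured analyses and write all artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: Dict[str, pd.DataFrame] = {}
    summary: Dict[str, object] = {"seed": config.seed, "error_model": config.error_model}

    primary, failures = run_primary(inputs, config)
    primary.to_csv(out / "effects_primary.csv", index=False)
    results["primary"] = primary
    summary["primary_failures"] = failures

    if combined:
        sec, sec_fail = run_secondary_combined(inputs, config)
        sec.to_csv(out / "effects_combined.csv", index=False)
        results["combined"] = sec
        summary["combined_failures"] = sec_fail

    if sensitivity:
        for name, (table, fails) in run_sensitivity(inputs, config).items():
            table.to_csv(out / f"effects_sensitivity_{name}.csv", index=False)
            results[f"sensitivity_{name}"] = table
            conc = concordance(primary, table)
            conc.to_csv(out / f"concordance_{name}.csv", index=False)
            summary[f"sensitivity_{name}_failures"] = fails
            summary[f"sensitivity_{name}_sign_agreement"] = (
                float(conc["same_sign"].mean()) if len(conc) else None
            )

    (out / "run_summary.json").write_text(json.dumps(summary, indent=1, default=str))
    return results


def study_config_from_yaml(path) -> StudyConfig:
    """Load a StudyConfig from a YAML file (keys as in the dataclass)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "calendar" in raw:
        c = raw["calendar"]
        raw["calendar"] = Calendar(
            start_date=pd.Timestamp(c["start_date"]).date(),
            n_weeks=int(c["n_weeks"]),
            announcement_week=int(c["announcement_week"]),
            implementation_week=int(c["implementation_week"]),
        )
    if "small_manufacturer_thresholds" in raw:
        raw["small_manufacturer_thresholds"] = tuple(raw["small_manufacturer_thresholds"])
    if "easter_categories" in raw:
        raw["easter_categories"] = frozenset(raw["easter_categories"])
    if "analyses" in raw:
        raw["analyses"] = tuple(raw["analyses"])
    return StudyConfig(**raw)
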