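"""Shared builders for compact synthetic configurations used across tests."""

from __future__ import annotations

from datetime import date

from sdil.synthetic import CategoryProcessSpec, SimulationConfig
from sdil.weeks import Calendar, default_calendar


def small_calendar(n_weeks: int = 40, announcement: int = 12, implementation: int = 26) -> Calendar:
    """A short week grid for fast simulation tests."""
    return Calendar(
        start_date=date(2014, 2, 24),
        n_weeks=n_weeks,
        announcement_week=announcement,
        implementation_week=implementation,
    )


def spec(label: str = "high_tier", baseline: float = 500.0, **kw) -> CategoryProcessSpec:
    return CategoryProcessSpec(category_label=label, baseline_level=baseline, **kw)


def control_spec(**kw) -> CategoryProcessSpec:
    return CategoryProcessSpec(category_label="toiletries", baseline_level=123.0, **kw)


def config(
    specs: dict | None = None,
    n_households: int = 5,
    calendar: Calendar | None = None,
    seed: int = 0,
    **kw,
) -> SimulationConfig:
    if specs is None:
        specs = {"high_tier": spec(), "toiletries": control_spec()}
    return SimulationConfig(
        n_households=n_households,
        calendar=calendar or default_calendar(),
        category_specs=specs,
        seed=seed,
        **kw,
    )


def noiseless_recovery_config(seed: int = 3) -> SimulationConfig:
    """Noiseless panel injecting +30.8 mL at announcement and -171.6 mL at
    implementation for high tier drinks, so the implementation-only analysis
    recovers -171.6 and the whole-intervention analysis recovers -140.8."""
    specs = {
        "high_tier": spec(
            baseline=980.0,
            weekly_trend=-1.5,
            seasonal_amplitude=60.0,
            christmas_uplift=50.0,
            announcement_level_change=30.8,
            implementation_level_change=-171.6,
            sugar_g_per_100=11.1,
        ),
        "toiletries": control_spec(),
    }
    return config(specs, n_households=4, seed=seed)


def noisy_recovery_config(seed: int = 0, n_households: int = 25) -> SimulationConfig:
    """AR(1) panel (rho = 0.5) with injected level and slope changes at both
    interruptions, plus a mildly noisy control category."""
    specs = {
        "high_tier": spec(
            baseline=980.0,
            weekly_trend=-1.5,
            seasonal_amplitude=60.0,
            christmas_uplift=50.0,
            announcement_level_change=20.0,
            announcement_slope_change=0.2,
            implementation_level_change=-120.0,
            implementation_slope_change=-1.0,
            noise_sd=30.0,
            household_sd=150.0,
            ar1_coefficient=0.5,
            sugar_g_per_100=11.1,
        ),
        "toiletries": control_spec(
            weekly_trend=-0.02,
            seasonal_amplitude=2.0,
            christmas_uplift=3.0,
            noise_sd=3.0,
            household_sd=25.0,
            ar1_coefficient=0.5,
        ),
    }
    return config(specs, n_households=n_households, seed=seed)
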