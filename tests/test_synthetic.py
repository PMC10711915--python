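"""Synthetic panel generator: determinism, ground truth, and consistency."""

import numpy as np
import pandas as pd
import pytest

from sdil import aggregate, study
from sdil.synthetic import (
    CategoryProcessSpec,
    DegenerateCounterfactualError,
    SimulationConfig,
    default_config,
    expected_path,
    simulate_catalogue,
    simulate_panel,
    true_effect,
)

from helpers import config, control_spec, small_calendar, spec


class TestConfigValidation:
    def test_control_category_required(self):
        with pytest.raises(ValueError, match="control"):
            config(specs={"high_tier": spec()})

    def test_easter_uplift_restricted_to_confectionery(self):
        with pytest.raises(ValueError, match="easter"):
            spec(label="high_tier", easter_uplift=10.0)
        CategoryProcessSpec("confectionery", 300.0, easter_uplift=40.0)  # fine

    def test_ar1_coefficient_bounds(self):
        with pytest.raises(ValueError):
            spec(ar1_coefficient=1.0)

    def test_negative_expected_path_is_config_error(self):
        cfg = config(
            specs={"high_tier": spec(baseline=10.0, weekly_trend=-1.0), "toiletries": control_spec()},
            calendar=small_calendar(),
        )
        with pytest.raises(ValueError, match="negative"):
            simulate_panel(cfg)


class TestDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = config(calendar=small_calendar(), seed=42)
        cat1 = simulate_catalogue(cfg)
        cat2 = simulate_catalogue(cfg)
        pd.testing.assert_frame_equal(cat1, cat2)
        ev1, wt1, _ = simulate_panel(cfg, cat1)
        ev2, wt2, _ = simulate_panel(cfg, cat2)
        pd.testing.assert_frame_equal(ev1, ev2)
        pd.testing.assert_frame_equal(wt1, wt2)

    def test_different_seed_differs(self):
        noisy = {"high_tier": spec(noise_sd=10.0), "toiletries": control_spec()}
        ev1, _, _ = simulate_panel(config(specs=noisy, calendar=small_calendar(), seed=1))
        ev2, _, _ = simulate_panel(config(specs=noisy, calendar=small_calendar(), seed=2))
        assert not np.allclose(ev1["quantity"], ev2["quantity"])


class TestCatalogue:
    def test_covers_categories_and_straddles_thresholds(self):
        cfg = default_config(n_households=2)
        cat = simulate_catalogue(cfg)
        for label in cfg.category_specs:
            assert (cat["intended_category"] == label).any()
        sugar = cat["sugar_g_per_100ml"].dropna()
        assert (sugar >= 8.0).any() and ((sugar >= 5.0) & (sugar < 8.0)).any() and (sugar < 5.0).any()
        assert cat["is_bottled_water"].any()
        assert (cat["milk_content_pct"] > 75).any()
        assert (cat["abv_pct"] > 1.2).any()
        assert (cat["physical_form"] == "powder").any()
        assert ((cat["juice_pct"] == 100) & cat["no_added_sugar"]).any()
        sizes = {m.size_class for m in cfg.manufacturers if m.manufacturer_id in set(cat["manufacturer_id"])}
        assert sizes == {"small", "large"}

    def test_classification_roundtrip_is_exact(self):
        """assign_category reproduces every product's intended category."""
        from sdil.classify import classify_catalogue

        cat = simulate_catalogue(default_config(n_households=2))
        labels = classify_catalogue(cat)
        intended = cat.set_index("product_id")["intended_category"]
        assert (labels.sort_index() == intended.sort_index()).all()


class TestNoiselessLimit:
    def test_household_values_follow_deterministic_path(self):
        cal = small_calendar()
        s = spec(baseline=400.0, weekly_trend=1.0, seasonal_amplitude=20.0, christmas_uplift=30.0)
        cfg = config(specs={"high_tier": s, "toiletries": control_spec()}, calendar=cal, n_households=3)
        cat = simulate_catalogue(cfg)
        events, _, truth = simulate_panel(cfg, cat)
        ids = set(cat.loc[cat["intended_category"] == "high_tier", "product_id"])
        ev = events[events["product_id"].isin(ids)]
        per_week = ev.groupby(["household_id", "week_start_date"])["quantity"].sum().unstack()
        expected = expected_path(s, cal)
        for _, row in per_week.iterrows():
            np.testing.assert_allclose(row.to_numpy(), expected, rtol=0, atol=1e-9)

    def test_noiseless_aggregation_reproduces_ground_truth(self):
        """The full aggregation pipeline returns the exact expected series."""
        cal = small_calendar()
        s = spec(baseline=400.0, weekly_trend=0.5, seasonal_amplitude=10.0,
                 implementation_level_change=-50.0)
        cfg = config(specs={"high_tier": s, "toiletries": control_spec()},
                     calendar=cal, n_households=4, seed=5)
        cat = simulate_catalogue(cfg)
        events, weights, truth = simulate_panel(cfg, cat)
        inputs = study.StudyInputs.from_frames(events, cat, weights)
        series = aggregate.weekly_weighted_mean(
            inputs.events, inputs.category_map, inputs.weights, "high_tier"
        )
        np.testing.assert_allclose(series.values, truth.expected_series("high_tier"), atol=1e-9)


class TestTrueEffect:
    def test_no_interruption_effects_give_zero(self):
        cfg = config(calendar=small_calendar())
        for week in (0, 15, 30):
            assert true_effect(cfg, "high_tier", 3, week) == (0.0, 0.0)

    def test_level_change_arithmetic(self):
        """Level change of -50 on a counterfactual of 200 is -25%."""
        s = spec(baseline=200.0, announcement_level_change=-50.0)
        cfg = config(specs={"high_tier": s, "toiletries": control_spec()}, calendar=small_calendar())
        absolute, relative = true_effect(cfg, "high_tier", 1, 20)
        assert absolute == -50.0
        assert relative == -25.0

    def test_combined_level_and_slope_closed_form(self):
        """Level -50 and slope -1/week, 30 weeks elapsed, counterfactual 400 -> (-80, -20%)."""
        cal = small_calendar(n_weeks=60, announcement=12, implementation=55)
        s = spec(baseline=400.0, announcement_level_change=-50.0, announcement_slope_change=-1.0)
        cfg = config(specs={"high_tier": s, "toiletries": control_spec()}, calendar=cal)
        absolute, relative = true_effect(cfg, "high_tier", 1, 12 + 30)
        assert absolute == pytest.approx(-80.0)
        assert relative == pytest.approx(-20.0)
        # cross-check against the explicit with/without path difference
        without = expected_path(spec(baseline=400.0), cal)
        with_ = expected_path(s, cal)
        assert (with_ - without)[42] == pytest.approx(absolute)

    def test_implementation_slope_accumulates_weekly(self):
        """Slope change -2/week evaluated 52 weeks later equals -104, the sum
        of weekly increments."""
        cal = small_calendar(n_weeks=80, announcement=10, implementation=20)
        s = spec(baseline=1000.0, implementation_slope_change=-2.0)
        cfg = config(specs={"high_tier": s, "toiletries": control_spec()}, calendar=cal)
        absolute, _ = true_effect(cfg, "high_tier", 2, 72)
        assert absolute == pytest.approx(-104.0)
        increments = sum(-2.0 for _ in range(52))  # one increment per elapsed week
        assert absolute == pytest.approx(increments)

    def test_analysis_id_selects_terms(self):
        s = spec(baseline=500.0, announcement_level_change=-30.0, implementation_level_change=-70.0)
        cfg = config(specs={"high_tier": s, "toiletries": control_spec()}, calendar=small_calendar())
        assert true_effect(cfg, "high_tier", 1, 30)[0] == -30.0
        assert true_effect(cfg, "high_tier", 2, 30)[0] == -70.0
        assert true_effect(cfg, "high_tier", 3, 30)[0] == -100.0

    def test_degenerate_counterfactual_raises(self):
        s = spec(baseline=40.0, announcement_level_change=50.0, weekly_trend=-1.2)
        cfg = config(specs={"high_tier": s, "toiletries": control_spec()}, calendar=small_calendar())
        with pytest.raises(DegenerateCounterfactualError):
            true_effect(cfg, "high_tier", 1, 39)  # counterfactual 40 - 1.2*39 < 0

    def test_week_outside_span_rejected(self):
        cfg = config(calendar=small_calendar())
        with pytest.raises(ValueError, match="span"):
            true_effect(cfg, "high_tier", 3, 40)

    def test_sugar_measure_scales_by_concentration(self):
        s = spec(baseline=500.0, implementation_level_change=-100.0, sugar_g_per_100=8.0)
        cfg = config(specs={"high_tier": s, "toiletries": control_spec()}, calendar=small_calendar())
        vol_abs, vol_rel = true_effect(cfg, "high_tier", 2, 30)
        sug_abs, sug_rel = true_effect(cfg, "high_tier", 2, 30, measure="sugar_mass")
        assert sug_abs == pytest.approx(vol_abs * 0.08)
        assert sug_rel == pytest.approx(vol_rel)


def test_monte_carlo_mean_converges_to_ground_truth():
    """Across 200 replicates the aggregated weekly mean matches the expected
    series within standard-error-scaled tolerance."""
    cal = small_calendar(n_weeks=30, announcement=10, implementation=20)
    s = spec(baseline=300.0, weekly_trend=1.0, seasonal_amplitude=15.0,
             implementation_level_change=-40.0, noise_sd=12.0, household_sd=25.0,
             ar1_coefficient=0.5)
    n_reps = 200
    base = config(specs={"high_tier": s, "toiletries": control_spec()},
                  calendar=cal, n_households=10)
    cat = simulate_catalogue(base)
    truth_path = None
    sums = np.zeros(cal.n_weeks)
    sums2 = np.zeros(cal.n_weeks)
    for rep in range(n_reps):
        cfg = config(specs=base.category_specs, calendar=cal, n_households=10, seed=10_000 + rep)
        events, weights, truth = simulate_panel(cfg, cat)
        inputs = study.StudyInputs.from_frames(events, cat, weights)
        series = aggregate.weekly_weighted_mean(
            inputs.events, inputs.category_map, inputs.weights, "high_tier"
        )
        sums += series.values
        sums2 += series.values**2
        truth_path = truth.expected_series("high_tier").to_numpy()
    mean = sums / n_reps
    se = np.sqrt((sums2 / n_reps - mean**2) / n_reps)
    z = (mean - truth_path) / se
    assert np.abs(z).max() < 5.0
    assert np.abs(z).mean() < 1.5
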