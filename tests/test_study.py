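"""Study orchestration: full runs, combined categories, sensitivity analyses."""

import numpy as np
import pandas as pd
import pytest

from sdil import study, synthetic
from sdil.study import StudyConfig, StudyInputs, concordance, run_primary, run_secondary_combined, run_sensitivity

from helpers import config, control_spec, noiseless_recovery_config, small_calendar, spec


def make_inputs(cfg):
    catalogue = synthetic.simulate_catalogue(cfg)
    events, weights, truth = synthetic.simulate_panel(cfg, catalogue)
    return StudyInputs.from_frames(events, catalogue, weights), truth


@pytest.fixture(scope="module")
def noiseless_run():
    cfg = noiseless_recovery_config()
    inputs, truth = make_inputs(cfg)
    scfg = StudyConfig(uncontrolled=True, min_weekly_purchases=0)
    table, failures = run_primary(inputs, scfg)
    return table, failures, truth


class TestRunPrimary:
    def test_completeness_every_combination_reported_once(self, noiseless_run):
        table, failures, _ = noiseless_run
        # high_tier: volume+sugar, toiletries is the control -> 2 measures x 3 analyses
        assert len(failures) == 0
        key = table[["category", "measure", "analysis"]].apply(tuple, axis=1)
        assert len(key) == len(set(key)) == 6

    def test_noiseless_injected_effects_recovered(self, noiseless_run):
        """Implementation-only analysis recovers -171.6 mL and the whole
        intervention recovers -140.8 mL, as injected."""
        table, _, _ = noiseless_run
        vol = table[(table.category == "high_tier") & (table.measure == "volume")]
        assert vol.set_index("analysis")["absolute_change"][2] == pytest.approx(-171.6)
        assert vol.set_index("analysis")["absolute_change"][3] == pytest.approx(-140.8)

    def test_missing_control_category_is_configuration_error(self):
        cfg = noiseless_recovery_config()
        inputs, _ = make_inputs(cfg)
        scfg = StudyConfig(control_category="confectionery", min_weekly_purchases=0)
        with pytest.raises(ValueError, match="control"):
            run_primary(inputs, scfg)

    def test_null_panel_cis_mostly_contain_zero(self):
        """With no injected effects, absolute-effect CIs behave nominally."""
        specs = {
            label: spec(label=label, baseline=base, noise_sd=base * 0.03,
                        household_sd=base * 0.2, ar1_coefficient=0.5,
                        seasonal_amplitude=base * 0.05,
                        sugar_g_per_100=conc)
            for label, base, conc in [
                ("high_tier", 900.0, 11.0), ("low_tier", 150.0, 6.5),
                ("bottled_water", 550.0, 0.0), ("exempt_juice", 500.0, 9.8),
            ]
        }
        specs["toiletries"] = control_spec(noise_sd=3.0, household_sd=20.0, ar1_coefficient=0.5)
        cfg = config(specs=specs, n_households=20, seed=31)
        inputs, _ = make_inputs(cfg)
        table, failures = run_primary(
            inputs, StudyConfig(min_weekly_purchases=0, analyses=(3,), error_model="ar1-gls")
        )
        assert len(failures) == 0
        contains_zero = (table.absolute_ci_low <= 0) & (0 <= table.absolute_ci_high)
        assert contains_zero.mean() >= 0.8


class TestRunSecondaryCombined:
    def test_combined_effect_is_sum_of_member_effects(self):
        """Noiseless panels: the combined-category estimate equals the sum of
        the member categories' injected effects (linearity)."""
        specs = {
            "high_tier": spec(baseline=900.0, weekly_trend=-1.0,
                              implementation_level_change=-150.0, sugar_g_per_100=11.0),
            "low_tier": spec(label="low_tier", baseline=300.0,
                             implementation_level_change=-50.0, sugar_g_per_100=6.5),
            "toiletries": control_spec(),
        }
        cfg = config(specs=specs, n_households=4, seed=9)
        inputs, _ = make_inputs(cfg)
        scfg = StudyConfig(uncontrolled=True, min_weekly_purchases=0, analyses=(2,))
        table, failures = run_secondary_combined(inputs, scfg)
        # only the empty <5 g band may fail on this two-tier catalogue
        assert {f["category"] for f in failures} <= {"band_lt5"}
        row = table[(table.category == "levy_liable") & (table.measure == "volume")].iloc[0]
        assert row["absolute_change"] == pytest.approx(-200.0)

    def test_sugar_band_membership_is_constant_without_reformulation(self):
        """With static concentrations the >=8 g band matches the high tier."""
        cfg = noiseless_recovery_config()
        inputs, _ = make_inputs(cfg)
        scfg = StudyConfig(uncontrolled=True, min_weekly_purchases=0, analyses=(2,))
        combined, _ = run_secondary_combined(inputs, scfg)
        primary, _ = run_primary(inputs, scfg)
        band = combined[(combined.category == "band_ge8") & (combined.measure == "volume")].iloc[0]
        high = primary[(primary.category == "high_tier") & (primary.measure == "volume")].iloc[0]
        assert band["absolute_change"] == pytest.approx(high["absolute_change"])


class TestRunSensitivity:
    def test_threshold_zero_is_identical_to_primary(self):
        cfg = noiseless_recovery_config()
        inputs, _ = make_inputs(cfg)
        scfg = StudyConfig(uncontrolled=True, min_weekly_purchases=0,
                           small_manufacturer_thresholds=(0.0,), analyses=(3,))
        primary, _ = run_primary(inputs, scfg)
        out = run_sensitivity(inputs, scfg)
        pd.testing.assert_frame_equal(out["exclude_small_0"][0], primary)

    def test_zero_volume_small_manufacturers_leave_run_unchanged(self):
        """If small manufacturers never appear in events, excluding them is a
        no-op."""
        cfg = noiseless_recovery_config()
        cfg.manufacturers = (
            synthetic.ManufacturerSpec("M_BIG1", 0.6, "large"),
            synthetic.ManufacturerSpec("M_BIG2", 0.4, "large"),
            synthetic.ManufacturerSpec("M_SMALL1", 0.0, "small"),
        )
        inputs, _ = make_inputs(cfg)
        # a panel-scale threshold: big manufacturers clear it, zero-volume ones do not
        scfg = StudyConfig(uncontrolled=True, min_weekly_purchases=0,
                           small_manufacturer_thresholds=(1.0,), analyses=(3,))
        primary, _ = run_primary(inputs, scfg)
        out = run_sensitivity(inputs, scfg)
        pd.testing.assert_frame_equal(out["exclude_small_1"][0], primary)

    def test_uncontrolled_fit_widens_intervals_with_informative_control(self):
        """When a market-wide disturbance loads on every category, dropping the
        control covariate widens absolute-effect CIs on average."""
        ratios = []
        for rep in range(10):
            specs = {
                "high_tier": spec(baseline=900.0, weekly_trend=-1.0,
                                  implementation_level_change=-100.0,
                                  noise_sd=4.0, ar1_coefficient=0.5,
                                  market_loading=4.0, sugar_g_per_100=11.0),
                "toiletries": control_spec(noise_sd=1.0, ar1_coefficient=0.5, market_loading=1.0),
            }
            cfg = config(specs=specs, n_households=10, seed=500 + rep, market_noise_sd=6.0)
            inputs, _ = make_inputs(cfg)
            scfg = StudyConfig(min_weekly_purchases=0, analyses=(3,))
            controlled, _ = run_primary(inputs, scfg)
            uncontrolled, _ = run_primary(inputs, StudyConfig(
                min_weekly_purchases=0, analyses=(3,), uncontrolled=True))
            c = controlled[(controlled.category == "high_tier") & (controlled.measure == "volume")].iloc[0]
            u = uncontrolled[(uncontrolled.category == "high_tier") & (uncontrolled.measure == "volume")].iloc[0]
            ratios.append(
                (u.absolute_ci_high - u.absolute_ci_low) / (c.absolute_ci_high - c.absolute_ci_low)
            )
        assert np.mean(ratios) > 1.0


class TestConcordance:
    def make_table(self, changes, significant):
        return pd.DataFrame(
            {
                "category": [f"c{i}" for i in range(len(changes))],
                "measure": "volume",
                "analysis": 3,
                "absolute_change": changes,
                "significant": significant,
            }
        )

    def test_sign_and_significance_agreement(self):
        a = self.make_table([-10.0, 5.0, -3.0], [True, True, False])
        b = self.make_table([-8.0, -2.0, -1.0], [True, False, False])
        out = concordance(a, b)
        assert out["same_sign"].tolist() == [True, False, True]
        assert out["same_significance"].tolist() == [True, False, True]

    def test_pure_function(self):
        a = self.make_table([-10.0], [True])
        b = self.make_table([-8.0], [True])
        pd.testing.assert_frame_equal(concordance(a, b), concordance(a, b))


class TestEndToEnd:
    def test_run_study_deterministic_outputs(self, tmp_path):
        """Two runs with the same panel and config write identical artifacts."""
        cfg = noiseless_recovery_config()
        inputs, _ = make_inputs(cfg)
        scfg = StudyConfig(uncontrolled=True, min_weekly_purchases=0, analyses=(3,),
                           small_manufacturer_thresholds=())
        study.run_study(inputs, scfg, tmp_path / "a", sensitivity=True, combined=False)
        study.run_study(inputs, scfg, tmp_path / "b", sensitivity=True, combined=False)
        for name in ("effects_primary.csv", "effects_sensitivity_no_control.csv"):
            assert (tmp_path / "a" / name).read_text() == (tmp_path / "b" / name).read_text()

    def test_cli_simulate_then_run(self, tmp_path):
        from click.testing import CliRunner

        from sdil.cli import main

        runner = CliRunner()
        panel = tmp_path / "panel"
        r1 = runner.invoke(main, ["simulate", "--seed", "1", "--out", str(panel),
                                  "--n-households", "6"])
        assert r1.exit_code == 0, r1.output
        assert (panel / "purchases.csv").exists() and (panel / "ground_truth.json").exists()

        out = tmp_path / "run"
        r2 = runner.invoke(main, ["run", "--panel", str(panel), "--analysis", "3",
                                  "--sensitivity", "none", "--no-combined",
                                  "--out", str(out), "--seed", "1"])
        assert r2.exit_code == 0, r2.output
        effects = pd.read_csv(out / "effects_primary.csv")
        assert len(effects) > 0
        assert set(effects["analysis"]) == {3}
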