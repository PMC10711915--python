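import pytest

from sdil import study, synthetic

from helpers import noisy_recovery_config


@pytest.fixture(scope="session")
def noisy_fit():
    """One controlled analysis-3 fit on a noisy panel, shared across tests."""
    cfg = noisy_recovery_config(seed=7)
    catalogue = synthetic.simulate_catalogue(cfg)
    events, weights, truth = synthetic.simulate_panel(cfg, catalogue)
    inputs = study.StudyInputs.from_frames(events, catalogue, weights)
    scfg = study.StudyConfig(min_weekly_purchases=0, analyses=(3,))
    series = study._series_for(inputs, "high_tier", "volume")
    control = study._control_series(inputs, scfg)
    return study.fit_one(series, scfg, 3, control)
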