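import pytest

from resbalance import ScenarioConfig, simulate


@pytest.fixture(scope="session")
def scenario():
    """One default synthetic campaign shared across read-only tests."""
    return simulate(ScenarioConfig(seed=7))


@pytest.fixture(scope="session")
def clean_scenario():
    """Noise-free, daily-sampled campaign (the lossless limit)."""
    return simulate(ScenarioConfig(seed=7, noise_cv=0.0, mean_sampling_gap=1.0))
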