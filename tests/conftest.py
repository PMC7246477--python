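import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from trafficimpact.synthetic import ScenarioConfig

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def flat_config(**overrides) -> ScenarioConfig:
    """Scenario with day-of-week and seasonal structure switched off.

    Useful when a test wants pre/post comparisons uncontaminated by the
    calendar composition of the two periods.
    """
    params = dict(dow_multipliers=np.ones(7), seasonal_amplitudes=((0.0, 0.0), (0.0, 0.0)))
    params.update(overrides)
    return ScenarioConfig(**params)


@pytest.fixture
def constant_noise_day():
    """One full day of 10-s samples at a constant 65 dBA."""
    ts = pd.date_range("2017-07-03", periods=8640, freq="10s")
    return pd.DataFrame({"timestamp": ts, "leq_dba": 65.0})
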