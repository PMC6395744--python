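import numpy as np
import pytest
from hypothesis import settings

from myodisc import SimulationConfig, generate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def default_config():
    return SimulationConfig(seed=1)


@pytest.fixture
def default_dataset(default_config):
    return generate_dataset(default_config)


@pytest.fixture
def clean_config():
    """Default design without noise or anomalies: rows equal group means."""
    from myodisc import MissingSpec, OutlierSpec

    return SimulationConfig(
        noise_cv=0.0, outlier_spec=OutlierSpec(count=0), missing_spec=MissingSpec(0), seed=1
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
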