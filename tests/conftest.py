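import numpy as np
import pytest

from tvor.pipeline import RunConfig
from tvor.stimulus import build_experiment_a, build_experiment_b


@pytest.fixture(scope="session")
def expa_platform():
    return build_experiment_a()


@pytest.fixture(scope="session")
def expb_platform():
    return build_experiment_b(start_condition="plantarflexion")


@pytest.fixture(scope="session")
def fast_config():
    """Analysis config with a lighter surrogate null for unit tests."""
    return RunConfig(n_surrogates=30)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
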