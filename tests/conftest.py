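import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import milkassoc as ma

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def dataset():
    """One full-size synthetic cohort shared across tests (default config)."""
    return ma.simulate(ma.default_config(seed=2022))


@pytest.fixture(scope="session")
def daughter_genotypes(dataset):
    daughters = list(dataset.phenotypes["animal"].unique())
    return dataset.genotypes.subset(animals=daughters)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
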