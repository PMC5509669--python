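import numpy as np
import pytest

from otaria.mcmc import FitData, MCMCConfig, sample_posterior
from otaria.simulate import generate_scenario


@pytest.fixture(scope="session")
def scenario():
    """Default synthetic scenario, shared across tests."""
    return generate_scenario(seed=0)


@pytest.fixture(scope="session")
def fit_data(scenario):
    return FitData(scenario.removals, scenario.observations.restrict(2013))


@pytest.fixture(scope="session")
def small_fit(fit_data):
    """A reduced-size posterior fit reused by evaluation/diagnostic tests."""
    cfg = MCMCConfig(n_iter=6000, burn_in=1000, thin=10, seed=11)
    return sample_posterior(fit_data, config=cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
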