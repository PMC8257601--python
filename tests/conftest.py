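import numpy as np
import pytest

from littertrace import nmr, synthetic


@pytest.fixture(scope="session")
def scenario():
    """Default noiseless scenario configuration."""
    return synthetic.ScenarioConfig(master_seed=0)


@pytest.fixture(scope="session")
def signatures():
    return nmr.load_signatures()


@pytest.fixture(scope="session")
def gas_bundle(scenario):
    """Noiseless gas table plus ground truth."""
    return synthetic.gen_respiration(scenario)


@pytest.fixture(scope="session")
def fraction_bundle(scenario):
    return synthetic.gen_fractions(scenario)


@pytest.fixture(scope="session")
def fame_bundle(scenario):
    return synthetic.gen_fame(scenario)


@pytest.fixture(scope="session")
def ion_bundle(scenario):
    return synthetic.gen_ion_stacks(scenario, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
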