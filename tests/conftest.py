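import numpy as np
import pytest

from srforest import ForestConfig, SimulationConfig, generate, restrict


@pytest.fixture(scope="session")
def model1_sample():
    """Moderate Model-1 identity sample shared across tests."""
    cfg = SimulationConfig(model=1, link="identity", p=5, n=2000, seed=42)
    return generate(cfg)


@pytest.fixture(scope="session")
def model1_restricted(model1_sample):
    return model1_sample.restricted()


@pytest.fixture(scope="session")
def small_forest(model1_restricted):
    """A small fitted forest for structural/oracle tests."""
    from srforest import fit_forest

    cfg = ForestConfig(num_trees=20, seed=7, validate_exponent=False)
    return fit_forest(model1_restricted, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
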