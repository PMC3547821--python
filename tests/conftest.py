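import numpy as np
import pytest

from evoaging import (
    EvolutionConfig,
    HazardFamily,
    HazardParams,
    run_evolution,
)
from evoaging.experiments import default_b_grid, default_hazard


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture(scope="session")
def hrm_params():
    return HazardParams(family=HazardFamily.HRM, a=1e-3, b=0.05)


@pytest.fixture(scope="session")
def htm_params():
    return HazardParams(family=HazardFamily.HTM, a=1e-3, b=0.05)


@pytest.fixture(scope="session")
def tiny_run():
    """A seconds-scale evolution run shared by smoke-level tests."""
    config = EvolutionConfig(N=50, G=20, replicates=5, seed=1, record_last=5)
    hazard = default_hazard(HazardFamily.HRM,
                            default_b_grid(HazardFamily.HRM)[2], N=config.N)
    return config, hazard, run_evolution(config, hazard)


def random_params(rng, family, with_ext=False):
    """Random but well-behaved hazard parameters for property tests."""
    a = 10 ** rng.uniform(-4, -2)
    b = 10 ** rng.uniform(-3, -1)
    k = rng.choice([1.0, 1.0, 2.0, 3.0])
    ext = 10 ** rng.uniform(-4, -3) if with_ext and rng.random() < 0.5 else 0.0
    return HazardParams(family=family, a=a, b=b, k=k, ext=ext)
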