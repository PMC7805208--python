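import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import adsim

settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")


@pytest.fixture(scope="session")
def case1():
    return adsim.load_case(1)


@pytest.fixture(scope="session")
def params(case1):
    return adsim.default_params(case1)


@pytest.fixture(scope="session")
def plant_runs():
    """Steady-state plant runs for case 1, one per operating concept.

    Session-scoped: these are the expensive simulations the behavioural
    assertions share.
    """
    return {mode: adsim.run_plant(adsim.build_configuration(mode, 1))
            for mode in adsim.MODES}


def random_liquid_state(rng: np.random.Generator) -> np.ndarray:
    """A random plausible liquid-phase composition for pH property tests."""
    from adsim.components import IDX, zero_liquid

    y = zero_liquid()
    y[IDX["S_ac"]] = rng.uniform(0, 10.0)
    y[IDX["S_pro"]] = rng.uniform(0, 5.0)
    y[IDX["S_bu"]] = rng.uniform(0, 3.0)
    y[IDX["S_va"]] = rng.uniform(0, 2.0)
    y[IDX["S_IC"]] = rng.uniform(0, 0.5)
    y[IDX["S_IN"]] = rng.uniform(0, 0.5)
    y[IDX["S_cat"]] = rng.uniform(0, 0.1)
    y[IDX["S_an"]] = rng.uniform(0, 0.1)
    return y
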