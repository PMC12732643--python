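import numpy as np
import pytest

import ra_cea as r
from ra_cea.parameters import LifeTable


@pytest.fixture(scope="session")
def params():
    return r.default_parameters()


@pytest.fixture(scope="session")
def strategies():
    """(intervention, comparator) pair."""
    return r.default_strategies()


@pytest.fixture(scope="session")
def life_table(params):
    return r.default_life_table(params)


@pytest.fixture(scope="session")
def base_results(params, strategies, life_table):
    si, sc = strategies
    return (
        r.run_strategy(si, params, life_table),
        r.run_strategy(sc, params, life_table),
    )


@pytest.fixture()
def zero_mortality_table():
    ages = np.arange(0, 111)
    return LifeTable(ages=ages, qx=np.zeros_like(ages, dtype=float))


@pytest.fixture()
def flat_qx_table():
    """Constant 5%/year death probability at every age."""
    ages = np.arange(0, 111)
    return LifeTable(ages=ages, qx=np.full(ages.shape, 0.05))
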