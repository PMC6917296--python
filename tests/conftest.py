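import numpy as np
import pytest

from bfhs import BetaPrior, toy_disease_hazard, toy_mortality_hazard

P0 = 0.197


@pytest.fixture(scope="session")
def disease():
    return toy_disease_hazard()


@pytest.fixture(scope="session")
def mortality():
    return toy_mortality_hazard()


@pytest.fixture(scope="session")
def prior():
    return BetaPrior(1.184, 4.828)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
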