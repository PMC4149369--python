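import numpy as np
import pytest

from gsam import GSAMSpec, hymenoptera
from gsam.terms import intercept, inverse_area_power, log_area_power


@pytest.fixture(scope="session")
def hym():
    return hymenoptera()


@pytest.fixture(scope="session")
def selected_spec():
    """The normal-family component selected for the Hymenoptera data:
    intercept + (ln A)^2 + 1/A on the lambda = 1 Box-Cox scale."""
    return GSAMSpec(terms=(intercept(), log_area_power(2),
                           inverse_area_power(1)),
                    family="normal", link="identity", lam=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240829)
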