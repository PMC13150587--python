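import numpy as np
import pytest

from enzopt import AMYLASE_FACTORS, fit_quadratic, load_amylase_bbd


@pytest.fixture(scope="session")
def amylase_table():
    return load_amylase_bbd()


@pytest.fixture(scope="session")
def amylase_fit(amylase_table):
    return fit_quadratic(amylase_table, "specific_activity")


@pytest.fixture(scope="session")
def factors():
    return AMYLASE_FACTORS


@pytest.fixture(scope="session")
def factor_box(factors):
    return [(f.low, f.high) for f in factors]


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
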