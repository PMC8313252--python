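import numpy as np
import pytest

from phytascreen.chromatogram import default_retention_table
from phytascreen.synthetic import make_substrate


@pytest.fixture(scope="session")
def rt():
    return default_retention_table()


@pytest.fixture(scope="session")
def clean_substrate():
    return make_substrate()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
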