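import numpy as np
import pytest

from pkadirect import benchmark as bench
from pkadirect import fixtures
from pkadirect import microsolvation as ms


@pytest.fixture(scope="session")
def phenol():
    return fixtures.phenol_template()


@pytest.fixture(scope="session")
def phenol_2w(phenol):
    return ms.place_waters(phenol, 2)


@pytest.fixture(scope="session")
def bundled_records():
    return bench.bundled_benchmark()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
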