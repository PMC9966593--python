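import numpy as np
import pytest

from drtworld.config import Params, default_sequence_defs


@pytest.fixture(scope="session")
def seq_defs():
    return default_sequence_defs(0)


@pytest.fixture()
def params():
    return Params()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
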