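import numpy as np
import pytest

from pametrics.questionnaires import default_met_table, default_pase_weights


@pytest.fixture(scope="session")
def met_table():
    return default_met_table()


@pytest.fixture(scope="session")
def pase_weights():
    return default_pase_weights()


@pytest.fixture()
def rng():
    return np.random.default_rng(20100316)
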