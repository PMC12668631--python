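import numpy as np
import pytest

import bootstraphear as bh


@pytest.fixture(scope="session")
def env():
    return bh.Environment()


@pytest.fixture(scope="session")
def lso_table():
    return bh.make_lso_table(32, seed=0)


@pytest.fixture(scope="session")
def pop_teacher(lso_table):
    return bh.PopulationTeacher(lso_table, side="right")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
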