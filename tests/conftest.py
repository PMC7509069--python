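import numpy as np
import pytest

import cogtrace as ct


@pytest.fixture(scope="session")
def q3():
    return ct.builtin_fixture("q3_20")


@pytest.fixture(scope="session")
def q6():
    return ct.builtin_fixture("q6_20")


@pytest.fixture(scope="session")
def q_emp():
    return ct.builtin_fixture("q_empirical")


@pytest.fixture(scope="session")
def trans3():
    return ct.builtin_fixture("transitions_k3")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def emp_net(q_emp):
    """SSOM trained to convergence on the separable empirical ideal responses."""
    X, y = ct.build_training_set(q_emp, size=80)
    cfg = ct.SSOMConfig(grid_shape=(9, 9), iterations=3)
    return ct.train(X, y, cfg, seed=7), X, y
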