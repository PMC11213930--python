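import numpy as np
import pytest

from hapticstrokes.analysis import segment_dataset
from hapticstrokes.simulate import SimParams, simulate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def exp1_small():
    """Two simulated participants of an experiment-1-style session.

    Mixture weight w(q) = q gives chance-level behaviour at q = 0 and a
    clear quality gradient, which several analysis tests rely on.
    """
    params = SimParams(weight_fn=lambda q: q)
    return simulate_experiment(1, 2, params, seed=11)


@pytest.fixture(scope="session")
def exp1_segmented(exp1_small):
    return segment_dataset(exp1_small.trajectories)
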