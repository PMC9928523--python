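import numpy as np
import pytest

import tipchron as tc


@pytest.fixture
def rng():
    return np.random.default_rng(20220)


@pytest.fixture
def three_tip_tree():
    # ((a, b) at 1000, c) at 3000; all tips modern
    return tc.TimeTree([4, 4, 3, -1, 3], [0.0, 0.0, 0.0, 3000.0, 1000.0], ["a", "b", "c"])


@pytest.fixture
def identity_curve():
    return tc.make_identity_curve(0.0, 60_000.0, step=10.0, sigma=1e-6)


@pytest.fixture
def small_dataset():
    """A 12-tip, 1 kb synthetic bundle used by several MCMC tests."""
    cfg = tc.SimulationConfig(n_tips=12, seq_length=1000, seed=99)
    return tc.make_study_like_dataset(cfg, 6)
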