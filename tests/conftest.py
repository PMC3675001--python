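import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params(rng):
    """Random small two-model parameter pair on the same basis."""
    from maxcauses import ModelParams

    D, H = 6, 4
    W = rng.standard_normal((D, H)) * 2.0
    return {
        "MCA": ModelParams(W=W, sigma=0.8, pi=0.3, model_kind="MCA"),
        "BSC": ModelParams(W=W, sigma=0.8, pi=0.3, model_kind="BSC"),
    }


def all_states(H):
    """Full binary state space, lexicographic."""
    import itertools

    return np.array(list(itertools.product([0, 1], repeat=H)), dtype=np.int8)
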