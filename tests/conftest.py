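import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def random_pair(rng, m, p_i=None, p_j=None):
    """A random presence-absence pair guaranteed not to be all-absent."""
    p_i = rng.uniform(0.2, 0.8) if p_i is None else p_i
    p_j = rng.uniform(0.2, 0.8) if p_j is None else p_j
    while True:
        y_i = (rng.random(m) < p_i).astype(np.int8)
        y_j = (rng.random(m) < p_j).astype(np.int8)
        if y_i.sum() or y_j.sum():
            return y_i, y_j
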