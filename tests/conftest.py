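import numpy as np
import pytest

from wavewire import RewiringConfig, init_random_digraph


@pytest.fixture
def small_graph():
    """A modest random digraph reused across structural tests."""
    return init_random_digraph(RewiringConfig(n=12, m=40, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
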