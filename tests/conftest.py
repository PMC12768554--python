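import numpy as np
import pytest

from chronolex import DecadeEmbeddings, DriftConfig, simulate_diachronic_embeddings


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_series():
    """A small drifting decade series shared across read-only tests."""
    return simulate_diachronic_embeddings(DriftConfig(n_words=40, n_changed=15, seed=11))


@pytest.fixture
def toy_embeddings():
    """Four hand-built 3-d vectors with known geometry."""
    vecs = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [1.0, 1.0, 0.0],
            [2.0, 0.0, 0.0],  # positive rescale of the first
        ]
    )
    return DecadeEmbeddings(1950, ["east", "north", "northeast", "east2"], vecs)
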