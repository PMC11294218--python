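import numpy as np
import pytest

from damgcn.montage import Montage, build_graph, load_standard_montage


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def tri_montage():
    # hand-computable distances: d12 = 5, d13 = 2, d23 = sqrt(29)
    return Montage(("a", "b", "c"), np.array([[0.0, 0, 0], [3, 4, 0], [0, 0, 2]]))


@pytest.fixture(scope="session")
def deap_graph():
    return build_graph(load_standard_montage("deap32"))


@pytest.fixture()
def small_features(rng):
    """Tiny random DE-like tensor: 24 samples x 5 channels x 3 bands with
    linearly separable labels planted in one cell."""
    x = rng.normal(size=(24, 5, 3))
    y = (np.arange(24) % 2).astype(int)
    x[y == 1, 2, 1] += 3.0
    return x, y
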