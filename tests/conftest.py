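import numpy as np
import pytest

from immigrate.core import NeighborWeights
from immigrate.data import LabeledDataset


@pytest.fixture
def four_point():
    """Two tight same-class pairs separated along feature 1."""
    X = np.array([[0.0, 0.0], [0.0, 1.0], [3.0, 0.0], [3.0, 1.0]])
    y = np.array(["a", "a", "b", "b"])
    return LabeledDataset(X, y)


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


def random_dataset(rng, n_per_class=6, a=3, shift=1.0):
    X = np.vstack(
        [
            rng.normal(0.0, 1.0, size=(n_per_class, a)),
            rng.normal(shift, 1.0, size=(n_per_class, a)),
        ]
    )
    y = np.array([0] * n_per_class + [1] * n_per_class)
    return LabeledDataset(X, y)


def uniform_neighbor_weights(data):
    """Uniform alpha/beta over each instance's hit and miss sets."""
    hs, ms, al, be = [], [], [], []
    for n in range(data.n_samples):
        h = data.hit_indices(n)
        m = data.miss_indices(n)
        hs.append(h)
        ms.append(m)
        al.append(np.full(len(h), 1.0 / len(h)))
        be.append(np.full(len(m), 1.0 / len(m)))
    return NeighborWeights(hs, ms, al, be)
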