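import numpy as np
import pytest

from mganet.channel_graph import Montage, build_knn_adjacency, default_montage
from mganet.synthetic_psg import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def graph6():
    """k=3 nearest-neighbour graph over the packaged 6-channel montage."""
    return build_knn_adjacency(default_montage(), k=3)


@pytest.fixture()
def square_montage():
    """Four channels at the corners of a unit square (z = 0)."""
    return Montage(
        channel_names=("a", "b", "c", "d"),
        coordinates=np.array(
            [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [1.0, 1.0, 0.0], [0.0, 1.0, 0.0]]
        ),
    )


@pytest.fixture(scope="session")
def dataset_small():
    """A 400-epoch simulated recording for fast pipeline tests."""
    return generate_dataset(SimulationConfig(n_epochs=400, seed=42))


@pytest.fixture(scope="session")
def dataset_default():
    """The default study-scale simulated recording (2000 epochs, seed 42)."""
    return generate_dataset(SimulationConfig(n_epochs=2000, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
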