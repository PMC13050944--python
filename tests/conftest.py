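import numpy as np
import pytest

from prestate import synth
from prestate.montage import channel_positions, neighborhood


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def nbhd3():
    return neighborhood(k=3)


@pytest.fixture(scope="session")
def elec_positions():
    return channel_positions()


@pytest.fixture(scope="session")
def small_truth():
    """4 planted orthogonal maps, 3 subjects x 3 conditions, moderate SNR."""
    return synth.make_ground_truth(n_maps=4, n_subjects=3, n_conditions=3, seed=99,
                                   snr=3.0)


@pytest.fixture(scope="session")
def small_epochs(small_truth):
    return synth.generate_epochs(small_truth, n_subjects=3, n_conditions=3,
                                 n_trials=4)


@pytest.fixture(scope="session")
def tiny_leadfield(elec_positions):
    from prestate import sources

    return sources.build_leadfield(elec_positions, grid_spacing_mm=20.0)
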