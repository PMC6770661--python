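import numpy as np
import pytest

import membpos as mp


@pytest.fixture(scope="session")
def class_a_system():
    """Small noise-free class-A synthetic system (trajectory, truth, segmap)."""
    spec = mp.class_a_spec(n_frames=5, grid_n=6)
    return mp.emit_trajectory(spec)


@pytest.fixture(scope="session")
def class_b_system():
    spec = mp.class_b_spec(n_frames=5, grid_n=6)
    return mp.emit_trajectory(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
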