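import numpy as np
import pytest
from hypothesis import settings

from mese_relaxo.acquisition import (
    add_rician_noise,
    generate_phantom,
    three_ring_phantom_spec,
    tomato_protocol,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

#: Phantom ring truth: amplitude and T2 (ms) per ring label.
RING_TRUTH = {1: (250.0, 80.0), 2: (250.0, 200.0), 3: (250.0, 600.0)}


@pytest.fixture(scope="session")
def te61():
    """The 61-echo fruit-protocol grid, TE = 30..1830 ms."""
    return tomato_protocol().te_grid


@pytest.fixture(scope="session")
def phantom_small():
    """Noiseless 64x64x45 three-ring phantom with its label map."""
    spec = three_ring_phantom_spec(shape=(64, 64))
    return generate_phantom(spec, n_echo=45)


@pytest.fixture(scope="session")
def phantom_equal_area_61():
    """Noiseless 128x128x61 equal-area phantom (mixture-curve fixture)."""
    spec = three_ring_phantom_spec(shape=(128, 128), equal_area=True)
    return generate_phantom(spec, n_echo=61)


@pytest.fixture(scope="session")
def noisy_phantom_small(phantom_small):
    """The small phantom with sigma=10 Rician noise, fixed seed."""
    stack, labels = phantom_small
    return add_rician_noise(stack, 10.0, seed=7), labels


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
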