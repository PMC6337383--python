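import numpy as np
import pytest

from sbpharm import dynophore, synthetic_data


@pytest.fixture(scope="session")
def pocket_bundle():
    return synthetic_data.gen_toy_pocket(seed=0)


@pytest.fixture(scope="session")
def pocket_model(pocket_bundle):
    """Pharmacophore model perceived from the planted pocket frame."""
    frames, _ = synthetic_data.gen_trajectory(pocket_bundle, n_frames=1, toggles={}, seed=0)
    return dynophore.perceive_features(frames[0])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng):
    return synthetic_data.random_rotation(rng)
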