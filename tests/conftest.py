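import numpy as np
import pytest

import noisymix as nm
from noisymix.training import TrainConfig, train


@pytest.fixture(scope="session")
def small_scenes():
    """60 six-class scenes with 1-3 disjoint objects each."""
    return nm.generate_dataset(nm.SceneSpec(seed=7), 60)


@pytest.fixture(scope="session")
def tiny_model():
    """An untrained six-class model (deterministic init)."""
    return nm.AFCMModel(6, seed=0)


@pytest.fixture(scope="session")
def trained_model_and_scenes():
    """A briefly trained model whose CAMs localize the planted shapes.

    12 epochs of plain BCE on 200 clean scenes (~10 s) is enough for the
    activation maps to lock onto the objects.
    """
    scenes = nm.generate_dataset(nm.SceneSpec(seed=5), 200)
    model = nm.AFCMModel(6, seed=0)
    train(model, scenes, TrainConfig(epochs=12, lr=0.1, seed=0),
          method="baseline")
    return model, scenes


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
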