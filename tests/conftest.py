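import numpy as np
import pytest

from efeglean import model_core as mc
from efeglean.training import TrainConfig, TrainedModel, train_model
from efeglean.tmaze_envs import make_training_set
from efeglean.runner import EXPERIMENTS


@pytest.fixture(scope="session")
def tiny_spec():
    return mc.ModelSpec(
        layers=(mc.LayerConfig(4, 2, 2.0, 0.2), mc.LayerConfig(3, 2, 4.0, 0.5)),
        obs_dim=3, goal_dim=2, proprio_dim=2)


@pytest.fixture(scope="session")
def tiny_weights(tiny_spec):
    w = mc.ModelWeights(tiny_spec, seed=7)
    w.freeze()
    return w


@pytest.fixture(scope="session")
def tiny_frozen_model(tiny_spec, tiny_weights):
    """An untrained but frozen model for planner-mechanics tests."""
    B, T = 1, 6
    A_mu = [np.zeros((B, T, c.num_z)) for c in tiny_spec.layers]
    A_sig = [np.zeros((B, T, c.num_z)) for c in tiny_spec.layers]
    from efeglean.training import TrainTrace
    return TrainedModel(tiny_weights, A_mu, A_sig, TrainTrace())


@pytest.fixture(scope="session")
def exp1_dataset():
    return make_training_set(1, seed=0)


@pytest.fixture(scope="session")
def exp1_quick_model(exp1_dataset):
    """Discrete-maze model trained on a reduced epoch budget: enough for
    coherent sampling and replanning behaviour, small enough for the
    default test run."""
    return train_model(exp1_dataset.batch, EXPERIMENTS[1].spec,
                       TrainConfig(epochs=8000, seed=0))
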