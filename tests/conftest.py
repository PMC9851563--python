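import numpy as np
import pytest

from hebbgate.learning_motifs import train
from hebbgate.network_core import TrainConfig


@pytest.fixture(scope="session")
def vanilla_interleaved_run():
    """One full-scale baseline run (interleaved, eps=0.2, 10,000 trials)."""
    return train(TrainConfig(variant="vanilla", curriculum="interleaved",
                             epsilon=0.2, n_per_task=5000, seed=0))


@pytest.fixture(scope="session")
def baseline_interleaved_runs():
    """20 seeded full-scale baseline interleaved runs (shared across tests)."""
    return [train(TrainConfig(variant="vanilla", curriculum="interleaved",
                              epsilon=0.2, n_per_task=5000, seed=s))
            for s in range(20)]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
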