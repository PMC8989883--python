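import numpy as np
import pytest

from paleoshuffle.synthetic_data import fig1_replay
from paleoshuffle.pipeline import recover_history


@pytest.fixture(scope="session")
def replay42():
    """The canonical replay dataset (seed 42), shared across the suite."""
    return fig1_replay(seed=42)


@pytest.fixture(scope="session")
def recovery42(replay42):
    """Full history recovery on the seed-42 replay."""
    return recover_history(replay42, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
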