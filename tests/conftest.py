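import numpy as np
import pytest

from lfpdecode import SyntheticConfig, extract_session_features, generate_session


@pytest.fixture(scope="session")
def small_session():
    """A compact signal-bearing session (12 trials, default coupling)."""
    config = SyntheticConfig(n_trials=12, seed=7)
    trials, truth = generate_session(config)
    return trials, truth


@pytest.fixture(scope="session")
def small_features(small_session):
    trials, _ = small_session
    return extract_session_features(trials)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
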