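import numpy as np
import pytest

from muhit import SessionConfig, generate_session


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """One modest modulated session shared by read-only tests."""
    cfg = SessionConfig(n_trials=6, n_channels=2,
                        channel_categories=("paw", "none"), seed=42)
    return generate_session(cfg)


@pytest.fixture(scope="session")
def null_session():
    """Session with no class information (modulation 1, equal background)."""
    cfg = SessionConfig.null(seed=7, n_trials=6)
    return generate_session(cfg)
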