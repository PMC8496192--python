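import numpy as np
import pytest

from gaitmod import SessionConfig, generate_session, preprocess_recording


@pytest.fixture(scope="session")
def beta_session():
    """Session with strong 20-25 Hz modulation at preferred phase 0."""
    cfg = SessionConfig(
        duration_s=100.0, fs=256.0, cycle_jitter_sd_s=0.05, seed=3,
        modulation_bands=((20.0, 25.0, 0.8, 0.0),),
    )
    return generate_session(cfg)


@pytest.fixture(scope="session")
def beta_session_pre(beta_session):
    """The same session after the default filter chains."""
    return preprocess_recording(beta_session.recording)


@pytest.fixture(scope="session")
def zero_jitter_session():
    cfg = SessionConfig(
        duration_s=60.0, fs=256.0, cycle_jitter_sd_s=0.0, seed=7,
    )
    return generate_session(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
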