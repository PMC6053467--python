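import numpy as np
import pytest

from fourhz import behavior, synthetic


@pytest.fixture(scope="session")
def behavior_session():
    """20-trial synthetic T-maze session shared across tests."""
    track, trials, truth = synthetic.gen_behavior_session(20, run_speed=20.0, seed=7)
    return track, trials, truth


@pytest.fixture(scope="session")
def linearized(behavior_session):
    track, trials, _ = behavior_session
    return behavior.linearize_session(track, trials)


@pytest.fixture(scope="session")
def small_lfp():
    """100 s coupled LFP pair at 500 Hz for spectral/phase tests."""
    return synthetic.gen_lfp_pair(100.0, 500.0, coupling=0.8, noise_sd=2.0, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
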