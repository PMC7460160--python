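import numpy as np
import pytest

from hradapt.simulate import ProtocolConfig, SimParticipant, simulate_session


@pytest.fixture(scope="session")
def participant():
    return SimParticipant(age=6.0, resting_hr=80.0, seed=1)


@pytest.fixture(scope="session")
def short_protocol():
    """Two-minute play session (40 s per scenario) for fast end-to-end tests."""
    return ProtocolConfig(play_duration_s=120.0)


@pytest.fixture(scope="session")
def uas_log(participant, short_protocol):
    return simulate_session(participant, "UAS", protocol=short_protocol, seed=11)


@pytest.fixture(scope="session")
def cis_log(participant, short_protocol):
    return simulate_session(participant, "CIS", protocol=short_protocol, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
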