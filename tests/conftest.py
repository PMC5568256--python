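import pytest

from cumeta import cumulate, load_fixture


@pytest.fixture(scope="session")
def knee_trials():
    return load_fixture("knee13")


@pytest.fixture(scope="session")
def knee_states(knee_trials):
    return cumulate(knee_trials)


@pytest.fixture(scope="session")
def final_state(knee_states):
    return knee_states[-1]
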