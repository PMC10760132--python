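import numpy as np
import pytest

import tmrsim as tm


@pytest.fixture(scope="session")
def nap30():
    """A 30-min default-parameter recording shared across detector tests."""
    hyp = tm.generate_hypnogram(30, seed=3)
    return tm.generate_eeg(hyp, seed=4)


@pytest.fixture(scope="session")
def stimuli():
    return tm.build_stimuli(seed=11)


@pytest.fixture(scope="session")
def session30(nap30, stimuli):
    """Closed-loop run over the 30-min recording with a default plan."""
    plan = tm.build_cue_plan(stimuli, seed=12)
    log = tm.run_session(nap30, plan, seed=13)
    return plan, log


@pytest.fixture(scope="session")
def behavior34(stimuli):
    """One 34-subject behavioral dataset at the default effect structure."""
    return tm.simulate_behavior(stimuli, n_subjects=34, seed=21)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
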