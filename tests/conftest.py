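import numpy as np
import pytest

import ssvepbf as s


@pytest.fixture(scope="session")
def montage32():
    return s.montage_32()


@pytest.fixture(scope="session")
def montage129():
    return s.montage_129()


@pytest.fixture(scope="session")
def schedule():
    return s.make_trial_schedule(1)


@pytest.fixture(scope="session")
def clean_epochs(montage32, schedule):
    """30 acquisition epochs of signal + 1/f noise, no artifacts."""
    ep = s.simulate_subject_epochs(
        schedule, montage32, s.GroundTruthEffect.null(), s.EegNoiseParams(), seed=11
    )
    ep.data = ep.data[:30]
    ep.labels = ep.labels.iloc[:30].reset_index(drop=True)
    return ep


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
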