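import numpy as np
import pytest

from vocalps import synthetic
from vocalps.core_signals import LAB_FS


@pytest.fixture(scope="session")
def small_lab_spec():
    """One vowel, one pitch, one trial: fast but full-featured session."""
    return synthetic.ParticipantSpec(
        vowels=("a",), pitches=("comfortable",),
        n_trials=1, syllables_per_trial=5, seed=11,
    )


@pytest.fixture(scope="session")
def small_lab_session(small_lab_spec):
    return synthetic.synthesize_lab_session(small_lab_spec)


@pytest.fixture(scope="session")
def small_day():
    """~72-second daylong stream with ~30% voicing."""
    spec = synthetic.ParticipantSpec(seed=7)
    return synthetic.synthesize_day(spec, duration_h=0.02, voiced_fraction=0.3, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def lab_fs():
    return LAB_FS
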