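import logging

import numpy as np
import pytest

from eegmicrostates import (
    EEGRecording,
    make_prototypes,
    simulate_eeg,
    simulate_label_sequence,
)
from eegmicrostates.synthetic import default_transition_matrix

logging.getLogger("eegmicrostates").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def prototypes64():
    """Four well-separated generating topographies on 64 channels."""
    return make_prototypes(64, 4, seed=0)


@pytest.fixture(scope="session")
def default_tp():
    return default_transition_matrix()


@pytest.fixture(scope="session")
def noiseless_subject(prototypes64, default_tp):
    """20 s noiseless recording with known labels (random polarity)."""
    seq = simulate_label_sequence(default_tp, [80, 85, 93, 68], 250.0, 5000, seed=11)
    rec = simulate_eeg(prototypes64, seq, noise_sigma=0.0,
                       polarity_flip_prob=0.5, seed=12)
    return rec, seq


@pytest.fixture(scope="session")
def noisy_subject(prototypes64, default_tp):
    """20 s recording at the default sensor-noise level."""
    seq = simulate_label_sequence(default_tp, [80, 85, 93, 68], 250.0, 5000, seed=21)
    rec = simulate_eeg(prototypes64, seq, noise_sigma=0.3,
                       polarity_flip_prob=0.5, seed=22)
    return rec, seq


def recording_from_columns(columns, fs=250.0):
    """Build a tiny EEGRecording whose samples are the given column vectors."""
    return EEGRecording(data=np.asarray(columns, dtype=float).T, fs=fs)


@pytest.fixture
def tiny_recording():
    rng = np.random.default_rng(5)
    return EEGRecording(data=rng.standard_normal((8, 200)), fs=250.0)
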