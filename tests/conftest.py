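import sys
from pathlib import Path

import numpy as np
import pytest

# make the sibling oracle helpers importable regardless of invocation dir
sys.path.insert(0, str(Path(__file__).parent))

from eeg3wd.eeg_io import CANONICAL_CHANNELS, EEGRecording


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_recording(seed: int = 0, n_samples: int = 400, fs: float = 250.0,
                   label: int | None = 0, subject_id: str = "s") -> EEGRecording:
    gen = np.random.default_rng(seed)
    return EEGRecording(
        subject_id=subject_id,
        label=label,
        fs=fs,
        channels=CANONICAL_CHANNELS,
        data=gen.standard_normal((len(CANONICAL_CHANNELS), n_samples)),
        canonical=True,
    )


@pytest.fixture
def recording():
    return make_recording()
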