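import numpy as np
import pytest

from affectsync import SessionSpec, align_session, gen_session
from affectsync.core import EEG_CHANNELS, EEGRecording, TimeSeries


@pytest.fixture(scope="session")
def default_session():
    """One reactive session with a planted 2.37 s device lag."""
    return gen_session(SessionSpec(seed=1, sync_lag=2.37))


@pytest.fixture(scope="session")
def aligned_session(default_session):
    bundle, gt = default_session
    return align_session(bundle), gt


@pytest.fixture(scope="session")
def flat_session():
    return gen_session(SessionSpec(seed=2, eda_profile="flat"))


def make_eeg(values: np.ndarray, rate: float = 128.0,
             offset: float = 0.0) -> EEGRecording:
    """Wrap a samples x 14 array (or a 1-D signal tiled over channels)
    as an EEG recording."""
    if values.ndim == 1:
        values = np.tile(values[:, None], (1, len(EEG_CHANNELS)))
    return EEGRecording(TimeSeries(values, rate=rate, offset=offset,
                                   channel_labels=list(EEG_CHANNELS)))
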