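import numpy as np
import pytest

from erpauth.epoching import EpochSet
from erpauth.signal_io import EventTable, Recording


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def toy_recording(rng):
    """2-channel, 4 s recording at 64 Hz with known content."""
    data = rng.standard_normal((2, 256))
    return Recording(data=data, sfreq=64.0, channel_names=["c1", "c2"])


@pytest.fixture()
def toy_events():
    import pandas as pd

    return EventTable(pd.DataFrame({
        "onset_sample": [32, 96, 160],
        "subject_id": ["s00", "s00", "s01"],
        "task_id": ["P300-Selected"] * 3,
        "stimulus_class": ["target"] * 3,
    }))


@pytest.fixture()
def toy_epochs(rng):
    """Small EpochSet: 8 epochs x 3 channels x 65 timepoints at 64 Hz."""
    n_tp = 65
    times = -0.1 + np.arange(n_tp) / 64.0
    data = rng.standard_normal((8, 3, n_tp))
    labels = np.array(["a", "a", "a", "a", "b", "b", "b", "b"], dtype=object)
    return EpochSet(data=data, times=times, labels=labels, sfreq=64.0,
                    channel_names=["c1", "c2", "c3"])
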