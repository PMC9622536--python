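import numpy as np
import pytest

from errmon.containers import EpochSet


def make_epochs(
    data,
    times=None,
    channels=None,
    lock="response",
    reference="left_mastoid",
    trial_ids=None,
):
    """Hand-built EpochSet for unit tests."""
    data = np.asarray(data, float)
    n_tr, n_ch, n_s = data.shape
    if times is None:
        times = 2.0 * np.arange(n_s)
    if channels is None:
        channels = [f"ch{i}" for i in range(n_ch)]
    if trial_ids is None:
        trial_ids = np.arange(n_tr)
    return EpochSet(
        data=data, times=np.asarray(times, float), channels=list(channels),
        trial_ids=np.asarray(trial_ids), lock=lock, reference=reference,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def toy_sphere_16():
    """16 roughly evenly spread unit-sphere points (upper-biased)."""
    i = np.arange(16) + 0.5
    phi = np.arccos(1 - i / 16)
    theta = np.pi * (1 + 5**0.5) * i
    return np.c_[
        np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)
    ]
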