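import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gammaflow.containers import Recording

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def make_noise_recording(n_channels=4, duration_s=20.0, fs=500.0, seed=0,
                         groups=None, events=None):
    """Plain white-noise Recording for filter/segment tests."""
    g = np.random.default_rng(seed)
    n = int(duration_s * fs)
    data = g.standard_normal((n_channels, n))
    if groups is None:
        groups = ["MEG"] * n_channels
    if events is None:
        events = pd.DataFrame({"sample": [], "label": []})
    return Recording(data=data, channel_groups=np.array(groups, dtype=object),
                     sampling_rate=fs, events=events)


@pytest.fixture
def noise_recording():
    return make_noise_recording()
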