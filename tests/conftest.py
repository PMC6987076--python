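import numpy as np
import pytest

from ordirr.io import Recording
from ordirr.simulate import LogisticSpec, gaussian_ar_series, logistic_series


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture
def logistic_1000():
    """A noiseless fully-chaotic logistic orbit of length 1000."""
    return logistic_series(LogisticSpec(length=1000, seed=7))


def make_recording(data, rate=250.0, **meta):
    data = np.atleast_2d(np.asarray(data, float))
    labels = meta.pop("labels", None) or [f"ch{i:02d}" for i in range(data.shape[0])]
    return Recording(data=data, channel_labels=labels, sampling_rate=rate, **meta)


@pytest.fixture
def mixed_cohort(rng):
    """4 ramp channels + 4 iid-noise channels in one recording."""
    ramps = np.vstack([np.arange(200.0) + i for i in range(4)])
    noise = rng.standard_normal((4, 200))
    return [make_recording(np.vstack([ramps, noise]))]
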