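import numpy as np
import pytest

from dynhrv.rr_io import RRISeries


@pytest.fixture
def rng():
    return np.random.default_rng(20200812)


@pytest.fixture
def constant_series():
    """200 beats at a steady 800 ms (75 BPM)."""
    return RRISeries.from_intervals(np.full(200, 800.0))


@pytest.fixture
def gaussian_series(rng):
    """5000 beats of iid Gaussian RR intervals around 800 ms."""
    return RRISeries.from_intervals(800.0 + 30.0 * rng.standard_normal(5000))
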