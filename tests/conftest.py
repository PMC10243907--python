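import numpy as np
import pytest

from dyadsync import Recording, make_scale_grid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_grid():
    """Coarse grid spanning the task-relevant periods; keeps unit tests fast."""
    return make_scale_grid(2.0, 64.0, 24)


@pytest.fixture
def default_grid():
    return make_scale_grid()


def make_recording(data, rate=10.0, role="A"):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    labels = [f"CH{i + 1}" for i in range(data.shape[0])]
    return Recording(role, rate, data, labels)


@pytest.fixture
def noise_recording(rng):
    """Two-channel 120 s noise recording at 10 Hz."""
    return make_recording(rng.standard_normal((2, 1200)))
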