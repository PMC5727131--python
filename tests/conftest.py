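import numpy as np
import pytest

from cgmboost import SAMPLES_PER_DAY, GlucoseTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_day(rng):
    """Factory for plausible random CGM days (mmol/L, 288 samples)."""

    def make(low=3.0, high=14.0, smooth=False):
        day = rng.uniform(low, high, SAMPLES_PER_DAY)
        if smooth:
            kernel = np.ones(5) / 5
            day = np.convolve(day, kernel, mode="same")
        return day

    return make


@pytest.fixture
def two_day_trace(random_day):
    return GlucoseTrace("pt", np.concatenate([random_day(), random_day()]))


def xor_dataset():
    """Four 2-feature points with XOR labels; no single stump separates them."""
    X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 1.0], [1.0, 0.0]])
    y = np.array([1, 1, -1, -1])
    return X, y
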