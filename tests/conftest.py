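import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from drrforge.core import CTVolume, validate_volume

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_hu_volume(rng):
    """Small random integer-valued HU volume (integer HU keep sums exact)."""

    def _make(shape=(8, 8, 8), lo=-1000, hi=2000, spacing=(1.0, 1.0, 1.0)):
        data = rng.integers(lo, hi, size=shape).astype(float)
        return validate_volume(CTVolume(data=data, spacing=spacing))

    return _make


def make_water_column(length_mm=100.0, dy=0.5, n_side=4):
    """A homogeneous water (0 HU) volume whose y-extent is ``length_mm``."""
    ny = int(round(length_mm / dy))
    data = np.zeros((n_side, ny, n_side))
    return CTVolume(data=data, spacing=(1.0, dy, 1.0))


@pytest.fixture
def water_column():
    return make_water_column
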