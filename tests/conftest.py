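import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vasmotion import binaural_synth as bs

settings.register_profile(
    "default",
    derandomize=True,
    database=None,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def room():
    return bs.default_room()


@pytest.fixture(scope="session")
def ess_pair():
    """One-second 200 Hz - 20 kHz sweep and its inverse filter."""
    return bs.ess_generate(200.0, 20000.0, 1.0, bs.FS)


@pytest.fixture(scope="session")
def reverberant_set(room):
    """5-degree reverberant filter set at the default image-source order."""
    return bs.build_filter_set("reverberant", room=room)


@pytest.fixture(scope="session")
def impulse_set():
    """Unit-impulse 'filters' at every 5-degree azimuth (identity render)."""
    az = np.arange(-90.0, 91.0, 5.0)
    pairs = np.zeros((az.size, 2, 64))
    pairs[:, :, 0] = 1.0
    return bs.SpatialFilterSet(az, 5.0, bs.FS, pairs, "anechoic")
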