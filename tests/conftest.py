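import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import foamplug as fp

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def clean_kinetics():
    """Noise-free reference trajectory: rise at 10 mm/s to 100 mm, fall at
    2 mm/s."""
    return fp.SimKinetics(
        formation_rate=10.0,
        degradation_rate=2.0,
        max_length=100.0,
        start_time=0.0,
        noise_sigma=0.0,
        seed=0,
    )


@pytest.fixture
def clean_series(clean_kinetics):
    return fp.simulate_series(clean_kinetics, frame_interval=0.1)


@pytest.fixture
def small_render():
    """Small, fast rendering geometry: 400 px x 60 px at 0.25 mm/px."""
    return fp.SimRender(
        mm_per_pixel=0.25,
        tube_axis_length=400,
        tube_width=60,
        intensity_noise_sigma=0.02,
    )


@pytest.fixture
def geometry():
    return fp.TubeGeometry(inner_diameter_mm=4.0, inclination_deg=25.0, mm_per_pixel=0.25)


def series_from_lengths(lengths, dt=1.0):
    """Build a PlugLengthSeries from raw length samples (unit spacing)."""
    lengths = np.asarray(lengths, dtype=float)
    return fp.PlugLengthSeries(np.arange(lengths.size) * dt, lengths, source="simulated")
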