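import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from featreg import ImageVolume, StructureMask


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def textured_volume(shape=(24, 24, 24), seed=0, smooth=2.0, amplitude=100.0):
    """Smooth random texture: enough structure for NC/MI to lock onto."""
    from scipy.ndimage import gaussian_filter

    noise = np.random.default_rng(seed).normal(size=shape)
    data = gaussian_filter(noise, smooth)
    data *= amplitude / max(data.std(), 1e-12)
    return ImageVolume(data)


def ball_mask(shape, center, radius, spacing=(1.0, 1.0, 1.0)):
    idx = np.indices(shape, dtype=float)
    c = np.asarray(center, dtype=float)
    r2 = sum((idx[a] - c[a]) ** 2 for a in range(3))
    return StructureMask(r2 <= radius**2, spacing=spacing)
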