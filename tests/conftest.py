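import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.ndimage import gaussian_filter

from transitqa import DoseImage

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def smooth_field(seed: int, n: int | None = None, sigma: float = 4.0) -> DoseImage:
    """A random smooth non-negative dose plane, peak-normalized to 100."""
    rng = np.random.default_rng(seed)
    if n is None:
        n = int(rng.integers(14, 29))
    vals = gaussian_filter(rng.uniform(0.0, 1.0, (n, n)), sigma, mode="reflect")
    return DoseImage(100.0 * vals / vals.max())


@pytest.fixture
def uniform_pair():
    ref = DoseImage(np.full((5, 5), 100.0))
    ev = DoseImage(np.full((5, 5), 104.0))
    return ref, ev


@pytest.fixture
def random_image():
    return DoseImage(np.random.default_rng(0).uniform(5.0, 100.0, (21, 21)),
                     spacing=(1.0, 1.0), origin=(-10.0, -10.0))
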