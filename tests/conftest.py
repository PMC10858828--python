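import numpy as np
import pytest

import carpodyn as cd


@pytest.fixture(scope="session")
def healthy_spec():
    return cd.make_phantom_spec("healthy", "right", seed=7)


@pytest.fixture(scope="session")
def complete_spec():
    return cd.make_phantom_spec("complete_tear", "right", seed=3)


@pytest.fixture(scope="session")
def short_series():
    """A short healthy series (masks + truth) shared across tests."""
    spec = cd.make_phantom_spec("healthy", "right", seed=1, n_frames=30)
    frames, masks, truth = cd.generate_series(spec)
    return spec, frames, masks, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def disk_mask(radius_px=10, shape=(64, 64), center=None, label=4):
    """Rasterized disk test mask (pixel centres inside the circle)."""
    if center is None:
        center = (shape[0] / 2, shape[1] / 2)
    rr, cc = np.mgrid[:shape[0], :shape[1]]
    m = ((rr - center[0]) ** 2 + (cc - center[1]) ** 2) <= radius_px ** 2
    out = np.zeros(shape, dtype=np.uint8)
    out[m] = label
    return out


def random_convex_polygon(rng, n=12, radius=10.0, center=(0.0, 0.0)):
    from scipy.spatial import ConvexHull

    pts = center + rng.normal(scale=radius, size=(n, 2))
    return pts[ConvexHull(pts).vertices]
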