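import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ctpropseg.volume_io import CTVolume, LabelMask

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def sphere_mask(shape=(30, 40, 40), center=(15, 20, 20), radius=8) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cz, cy, cx = center
    return (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


@pytest.fixture
def sphere_label() -> LabelMask:
    return LabelMask(organ="liver", mask=sphere_mask())


@pytest.fixture
def sphere_volume(sphere_label) -> CTVolume:
    """Bright sphere (~120 HU) on a dark (-50 HU) noisy background."""
    rng = np.random.default_rng(42)
    hu = np.full(sphere_label.shape, -50.0)
    hu[sphere_label.mask] = 120.0
    hu += rng.normal(0, 5.0, size=hu.shape)
    return CTVolume(intensities=hu, scan_id="sphere")


def random_blob_mask(rng: np.random.Generator, h: int = 36, w: int = 36) -> np.ndarray:
    """A random small blob (union of 1-3 filled discs) on one slice."""
    mask = np.zeros((h, w), dtype=bool)
    for _ in range(rng.integers(1, 4)):
        cy, cx = rng.integers(8, h - 8), rng.integers(8, w - 8)
        r = rng.integers(2, 6)
        yy, xx = np.ogrid[:h, :w]
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask
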