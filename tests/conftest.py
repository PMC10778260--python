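import numpy as np
import pytest

from cbctresp import ImageSlice, PhantomConfig, generate_pair


def disk_slice(
    radius: float = 20.0,
    value: float = 100.0,
    background: float = 0.0,
    shape: tuple[int, int] = (101, 101),
    center: tuple[float, float] | None = None,
    spacing: tuple[float, float] = (1.0, 1.0),
) -> ImageSlice:
    """Noise-free disk on a uniform background."""
    if center is None:
        center = ((shape[0] - 1) / 2, (shape[1] - 1) / 2)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.full(shape, background, dtype=float)
    img[(rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2] = value
    return ImageSlice(img, spacing[0], spacing[1])


@pytest.fixture
def disk():
    return disk_slice()


@pytest.fixture
def identity_pair():
    """Noise-free phantom pair with all change factors 1."""
    cfg = PhantomConfig(noise_sd_hu=0.0)
    return generate_pair(cfg)


@pytest.fixture
def phantom_center():
    cfg = PhantomConfig()
    return int(cfg.center[0]), int(cfg.center[1])
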