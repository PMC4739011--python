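import numpy as np
import pytest


def disk_mask(radius: int, pad: int = 4) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    c = (n - 1) / 2
    yy, xx = np.mgrid[0:n, 0:n]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def random_blob(rng: np.random.Generator, radius: int = 20, pad: int = 8,
                amplitude: float = 0.3) -> np.ndarray:
    """Fourier-perturbed star-convex blob; always a single filled component."""
    n = 2 * (radius + pad) + 1
    c = (n - 1) / 2
    yy, xx = np.mgrid[0:n, 0:n]
    theta = np.arctan2(yy - c, xx - c)
    r = np.hypot(yy - c, xx - c)
    rad = np.full_like(theta, float(radius) * (1 - amplitude))
    for k in range(2, 6):
        rad = rad + amplitude * radius / k * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    return r <= rad


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


@pytest.fixture
def disk50() -> np.ndarray:
    return disk_mask(50)
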