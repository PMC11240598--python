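import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def rasterize_disk(radius: int, size: int | None = None) -> np.ndarray:
    size = size or (2 * radius + 9)
    yy, xx = np.mgrid[:size, :size]
    c = size / 2.0
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def rasterize_ellipse(a: float, b: float, angle_deg: float = 0.0,
                      size: int | None = None) -> np.ndarray:
    size = size or int(2 * max(a, b) + 9)
    yy, xx = np.mgrid[:size, :size]
    c = size / 2.0
    th = np.deg2rad(angle_deg)
    x = xx - c
    y = -(yy - c)
    u = np.cos(th) * x + np.sin(th) * y
    v = -np.sin(th) * x + np.cos(th) * y
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0
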