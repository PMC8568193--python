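import numpy as np
import pytest

from cemchron import RunConfig


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def cfg():
    return RunConfig()


@pytest.fixture
def fast_cfg():
    """Config with fewer transects, for slice-level tests."""
    return RunConfig(n_transects=50, rng_seed=3)


def make_annulus(size=220, r_inner=60, r_outer=80, centre=None):
    """Annulus whose luminance depends smoothly on radius only."""
    cx = cy = (size - 1) / 2 if centre is None else centre
    y, x = np.mgrid[0:size, 0:size]
    r = np.hypot(x - cx, y - cy)
    img = np.zeros((size, size))
    mask = (r >= r_inner - 6) & (r <= r_outer + 6)
    img[mask] = 1000.0 + 800.0 * np.cos(2 * np.pi * (r[mask] - r_inner) / 20.0)
    return img, (cx, cy)


def radial_value(r, r_inner=60):
    return 1000.0 + 800.0 * np.cos(2 * np.pi * (r - r_inner) / 20.0)


@pytest.fixture
def annulus():
    return make_annulus()
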