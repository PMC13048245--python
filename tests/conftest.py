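"""Shared fixtures: small synthetic images built at test time."""

import numpy as np
import pytest

from actin_dispersion import FixtureSpec, RasterImage, generate_fixture


@pytest.fixture(scope="session")
def single_filament():
    """One isolated bright filament (known 30 degree angle) plus one nucleus."""
    spec = FixtureSpec(n_filaments=1, orientation_mode_deg=30.0, orientation_kappa=1e6, seed=5)
    img, truth = generate_fixture(spec)
    return img, truth


@pytest.fixture(scope="session")
def standard_fixture():
    """A typical disordered field: 60 filaments, one nucleus, mild noise."""
    return generate_fixture(FixtureSpec(seed=3))


def make_rgb(h=64, w=64, value=0.0):
    return RasterImage(np.full((h, w, 3), value, dtype=np.float64))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
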