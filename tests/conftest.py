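import numpy as np
import pytest

import sdrsim as s


@pytest.fixture(scope="session")
def psf200():
    return s.GaussianPSF(200.0)


@pytest.fixture(scope="session")
def grid128():
    return s.Grid2D(128, 128, 32.5)


@pytest.fixture(scope="session")
def grid256():
    return s.Grid2D(256, 256, 32.5)


@pytest.fixture(scope="session")
def patterns256(grid256):
    return s.default_patterns(grid256)


@pytest.fixture(scope="session")
def bead_scene_stack(grid256, patterns256, psf200):
    """A small noiseless bead field and its simulated raw stack."""
    obj = s.make_bead_field(grid256, n_beads=6, seed=11, margin_nm=600.0)
    stack = s.simulate_sim_stack(obj, patterns256, psf200)
    return obj, stack


@pytest.fixture(scope="session")
def point_stack(grid256, patterns256, psf200):
    """Noiseless single point emitter at the grid center."""
    obj = s.make_point_source(grid256)
    return obj, s.simulate_sim_stack(obj, patterns256, psf200)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
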