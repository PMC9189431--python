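import numpy as np
import pytest

from embryoseg.io_config import CalibratedVolume
from embryoseg.simulate import scaled_down_params, simulate_embryo

ANISO_SPACING = (1.0, 0.2, 0.2)  # (dz, dy, dx) μm — the target acquisition geometry


@pytest.fixture(scope="session")
def small_embryo():
    """One clean half-scale embryo (4 cells, SNR 10) shared across tests."""
    params = scaled_down_params(n_cells=4, target_snr=10.0, seed=11)
    image, truth = simulate_embryo(params)
    return image, truth, params


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_volume(data, spacing=ANISO_SPACING):
    return CalibratedVolume(np.asarray(data, dtype=float), spacing)


@pytest.fixture
def gaussian_blob_volume():
    """A single anisotropic Gaussian blob centred at voxel (8, 32, 32)."""
    spacing = np.asarray(ANISO_SPACING)
    shape = (16, 64, 64)
    sigma_um = 1.2
    zz, yy, xx = np.indices(shape, dtype=float)
    coords = np.stack([zz * spacing[0], yy * spacing[1], xx * spacing[2]])
    centre = np.array([8, 32, 32]) * spacing
    r2 = sum((coords[i] - centre[i]) ** 2 for i in range(3))
    data = 100.0 * np.exp(-r2 / (2 * sigma_um**2))
    return make_volume(data), centre, sigma_um
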