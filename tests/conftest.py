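import numpy as np
import pytest
from hypothesis import settings as _hsettings

_hsettings.register_profile("deterministic", derandomize=True, deadline=None)
_hsettings.load_profile("deterministic")

from conetomo.phantom import PhantomParams, generate_phantom, add_noise
from conetomo.projection import ConicalGeometry, simulate_series


@pytest.fixture(scope="session")
def default_phantom():
    """The default terminal-patch phantom with its ground truth."""
    params = PhantomParams(seed=3)
    vol, truth = generate_phantom(params)
    return params, vol, truth


@pytest.fixture(scope="session")
def noisy_phantom(default_phantom):
    params, vol, truth = default_phantom
    return params, add_noise(vol, snr=5.0, seed=103), truth


@pytest.fixture(scope="session")
def small_recon_phantom():
    """A small through-slab-membrane phantom suitable for fast
    simulate/align/reconstruct tests."""
    params = PhantomParams(voxel_size=3.0, shape=(96, 96, 20),
                           slab_thickness=50.0, n_cytoplasmic=2,
                           n_tethered=0, n_docked=2, n_omega=1, n_coated=0,
                           n_gold=5, include_ribbon=False,
                           membrane_frac=0.62, seed=5)
    vol, truth = generate_phantom(params)
    return params, vol, truth


@pytest.fixture(scope="session")
def coarse_geometry():
    """A 55 degree cone sampled every 10 degrees: same geometry class,
    fewer views, for tests where per-view cost dominates."""
    return ConicalGeometry(azimuth_step_deg=10.0)


@pytest.fixture(scope="session")
def small_series(small_recon_phantom, coarse_geometry):
    _, vol, _ = small_recon_phantom
    return simulate_series(vol, coarse_geometry, image_shape=(145, 145))
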