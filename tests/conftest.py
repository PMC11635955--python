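import numpy as np
import pytest
from hypothesis import settings

from fusedcae.optics import (EmissionSpectrum, MetasurfaceSpec,
                             OpticalSystemSpec, PSFKernel, kernel_preset)
from fusedcae.phantoms import ExposureSettings, SourceImage, capture

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gauss_kernel_9():
    """Known smooth asymmetric 9x9 kernel for recovery tests."""
    y, x = np.mgrid[-4:5, -4:5]
    g = np.exp(-(x ** 2 + y ** 2) / 6.0)
    g[2, 6] += 0.5  # break symmetry so orientation errors are visible
    return PSFKernel(g / g.sum(), 0.5)


@pytest.fixture(scope="session")
def texture_kernel():
    """Designed 300 nm-period (texture-enhancing) system kernel."""
    return kernel_preset("k_xi3")


@pytest.fixture(scope="session")
def plain_system():
    return OpticalSystemSpec()


@pytest.fixture(scope="session")
def visible_spectrum():
    return EmissionSpectrum.uniform_visible()


@pytest.fixture
def noiseless_exposure():
    return ExposureSettings(t_cap_ms=20.0, bin_factor=1, noiseless=True)


@pytest.fixture(scope="session")
def delta_source():
    img = np.zeros((64, 64))
    img[32, 32] = 1.0
    return SourceImage(img, 0.5)
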