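import numpy as np
import pytest

from qpatmi import spectral_phantom as sph
from qpatmi.fluence_forward import DomainGrid, SourceModel


@pytest.fixture
def rng():
    return np.random.default_rng(20170527)


@pytest.fixture(scope="session")
def library():
    return sph.surrogate_spectra()


@pytest.fixture(scope="session")
def phantom():
    """The packaged 50x50 numerical phantom."""
    return sph.build_numerical_phantom()


@pytest.fixture(scope="session")
def small_phantom():
    """A coarse 12x12 version of the phantom (same 5x5 mm^2 physics)."""
    spec = sph.PhantomSpec(grid=DomainGrid(12, 12, 5.0 / 12))
    return sph.build_numerical_phantom(spec)


@pytest.fixture(scope="session")
def small_noiseless_images(small_phantom, library):
    return sph.simulate_images(small_phantom, library, SourceModel(),
                               noise=sph.NoiseModel(0.0, 0))


@pytest.fixture(scope="session")
def small_mus(small_phantom, library):
    return np.stack([small_phantom.mus_prime(library, lam)
                     for lam in sph.WAVELENGTHS_NM])
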