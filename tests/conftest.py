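import numpy as np
import pytest

from cyclofit import Spectrum


@pytest.fixture
def gaussian_spectrum():
    """A single unit-area Gaussian band on a fine wavenumber grid."""
    x = np.arange(3000.0, 3801.0, 2.0)
    mu, sig = 3400.0, 40.0
    y = np.exp(-0.5 * ((x - mu) / sig) ** 2) / (sig * np.sqrt(2 * np.pi))
    return Spectrum(x, y, modality="FTIR-ATR", temperature=290.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
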