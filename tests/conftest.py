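import numpy as np
import pytest

from nirpowder.core import SpectraSet, default_wavenumber_grid


@pytest.fixture
def small_spectra() -> SpectraSet:
    """Three synthetic spectra on a short decreasing grid."""
    rng = np.random.default_rng(42)
    wn = np.arange(5000.0, 4000.0 - 1, -8.0)
    a = 0.3 + 0.1 * rng.random((3, wn.size))
    return SpectraSet(["s1", "s2", "s3"], wn, a)


@pytest.fixture
def default_grid() -> np.ndarray:
    return default_wavenumber_grid()
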