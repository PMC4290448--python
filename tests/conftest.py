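import numpy as np
import pytest

from finchra import ModelParams, hvc_song


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def hvc_raster():
    return hvc_song(100, 1000.0)


@pytest.fixture(scope="session")
def tiny_weights():
    """A connectivity profile whose weights are numerically negligible,
    for isolating LMAN- or externally-driven dynamics."""
    from finchra.weights import ConnectivityProfile

    w = np.full(100, 1e-12)
    return ConnectivityProfile(rho=1.0, m=1e-12, s=0.0, weights=w)
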