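import numpy as np
import pytest

from reprorsf.grids import Landscape, generate_elevation, generate_landscape, slope_degrees, vrm


@pytest.fixture(scope="session")
def landscape64():
    """Small but full-featured landscape shared by the slower tests."""
    return generate_landscape(shape=(64, 64), seed=1234)


@pytest.fixture(scope="session")
def terrain128():
    """Elevation + derived terrain stack at the default analysis scale."""
    elev = generate_elevation((128, 128), seed=99)
    return Landscape(
        {"elevation": elev, "slope": slope_degrees(elev), "ruggedness": vrm(elev)}
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
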