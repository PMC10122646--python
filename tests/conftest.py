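import numpy as np
import pytest

from qmoct import Layer, LayeredObject, SpectralGrid, synthesize_spectrum


@pytest.fixture(scope="session")
def grid():
    return SpectralGrid()


@pytest.fixture(scope="session")
def fig1_object():
    """Four-interface object: front surface at 218 um optical distance,
    layers of 87, 44 and 306 um with GVD 5000, -4000, -2000 fs^2/mm."""
    return LayeredObject(
        front_distance_um=218.0,
        layers=(
            Layer(87.0, 5000.0, 0.6),
            Layer(44.0, -4000.0, 0.6),
            Layer(306.0, -2000.0, 0.6),
        ),
        front_reflectivity=0.6,
    )


@pytest.fixture(scope="session")
def single_reflector_spectrum(grid):
    """Noiseless spectrum of a lone reflector at 218 um."""
    obj = LayeredObject(front_distance_um=218.0, front_reflectivity=0.8)
    return synthesize_spectrum(obj, grid)
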