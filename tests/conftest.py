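import numpy as np
import pytest

from osdensity.basis import default_basis, toy_basis
from osdensity.records import (FitBounds, ScatteringParams, TissueComposition,
                               geometry_for_cup)


@pytest.fixture(scope="session")
def basis():
    return default_basis()


@pytest.fixture(scope="session")
def fast_basis():
    return toy_basis()


@pytest.fixture(scope="session")
def geometry():
    return geometry_for_cup("B")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def table1_composition():
    """Daughters' group-mean composition (water/lipid/collagen in percent,
    total Hb 0.61% split 70/30 oxy/deoxy)."""
    return TissueComposition(17.2, 46.0, 21.3, 0.7 * 0.61, 0.3 * 0.61)


@pytest.fixture(scope="session")
def typical_scattering():
    return ScatteringParams(1.7, 1.3)


@pytest.fixture(scope="session")
def bounds():
    return FitBounds()
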