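import numpy as np
import pytest

import v1maps as v


@pytest.fixture(scope="session")
def default_al():
    return v.ALParams.from_ratio(1.0)


@pytest.fixture(scope="session")
def default_rf():
    return v.RFParams.from_aspect(2.0)


@pytest.fixture(scope="session")
def hypercolumn():
    return v.generate_hypercolumn(v.hypercolumn_grid())


@pytest.fixture(scope="session")
def lattice3():
    """3x3 lattice at the default resolution (enough margin for pooling windows)."""
    return v.tile_lattice(3, 3)


@pytest.fixture(scope="session")
def lattice5_coarse():
    """5x5 lattice at a coarser pitch for fast spectral tests."""
    return v.tile_lattice(5, 5, dx=0.025)
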