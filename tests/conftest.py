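import numpy as np
import pytest

from ippm.io_core import GridSpec, Raster


@pytest.fixture
def grid16():
    return GridSpec(x0=0.0, y0=16 * 30.0, dx=30.0, dy=30.0, nx=16, ny=16,
                    years=(2000, 2001))


@pytest.fixture
def grid32():
    return GridSpec(x0=0.0, y0=32 * 30.0, dx=30.0, dy=30.0, nx=32, ny=32,
                    years=(2000, 2002))


@pytest.fixture
def ones_raster(grid16):
    return Raster(grid16, np.ones((16, 16)))


@pytest.fixture(scope="session")
def small_world():
    """A 24x24, 2-year synthetic world shared across read-only tests."""
    from ippm import synthetic_data as synth

    g = GridSpec(x0=0.0, y0=24 * 30.0, dx=30.0, dy=30.0, nx=24, ny=24,
                 years=(2000, 2001))
    return synth.simulate_world(g, seed=42, target_nests=400, target_ebird=120,
                                field_coarsen=2)
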