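import numpy as np
import pytest

from carcassdrift.drift_sim import Island
from carcassdrift.survey_data import load_table1
from carcassdrift.synthetic_data import toy_island
from carcassdrift.winds import WindGrid
from shapely.geometry import Polygon


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def island():
    """Circular 5-km-radius island at the origin."""
    return toy_island()


@pytest.fixture
def constant_wind():
    """Factory: spatially/temporally constant wind over a large domain."""

    def make(u: float, v: float, n_days: int = 20, extent: float = 400.0):
        times = np.arange(0.0, n_days * 24.0, 3.0)
        xs = np.linspace(-extent, extent, 9)
        ys = np.linspace(-extent, extent, 9)
        shape = (times.size, ys.size, xs.size)
        return WindGrid(times, xs, ys, np.full(shape, u), np.full(shape, v))

    return make


@pytest.fixture
def square_coast():
    """Island whose northern coast is the segment y=0, |x|<=10."""
    return Island(name="SQ", polygon=Polygon(
        [(-10, -20), (10, -20), (10, 0), (-10, 0)]
    ))
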