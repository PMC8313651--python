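import numpy as np
import pytest

import regqa as rq


def make_volume(values, spacing=(1.0, 1.0, 1.0), modality="CT"):
    values = np.asarray(values, float)
    if values.ndim == 1:                       # convenience: 1-D -> (1,1,n)
        values = values.reshape(1, 1, -1)
    return rq.ScalarVolume(values, spacing, modality=modality)


@pytest.fixture(scope="session")
def table1():
    return rq.load_fixture("table1")


@pytest.fixture(scope="session")
def table2():
    return rq.load_fixture("table2")


@pytest.fixture(scope="session")
def table4():
    return rq.load_fixture("table4")


@pytest.fixture(scope="session")
def y_thorax():
    """Noise-free thorax with a single tracheal bifurcation (Y topology)."""
    spec = rq.PhantomSpec(airway=rq.AirwayTreeSpec(branching_depth=1))
    return rq.make_thorax(spec)


@pytest.fixture(scope="session")
def straight_tube():
    """A vertical tube of air through a uniform body, 30 slices."""
    shape, spacing = (30, 24, 24), (1.5, 1.0, 1.0)
    values = np.full(shape, 0.0)
    zz, yy, xx = np.meshgrid(*(np.arange(n) * s
                               for n, s in zip(shape, spacing)), indexing="ij")
    lumen = ((yy - 12.0) ** 2 + (xx - 12.0) ** 2) <= 4.0 ** 2
    values[lumen] = -1000.0
    vol = rq.ScalarVolume(values, spacing)
    return vol, rq.BinaryMask(lumen, spacing)
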