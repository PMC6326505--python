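import numpy as np
import pytest

from paintbox import GridSpec, ImageVolume


@pytest.fixture
def unit_grid():
    return GridSpec(shape=(10, 10, 10), spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_volume(grid, values, kind="suv"):
    return ImageVolume(grid=grid, values=np.asarray(values, dtype=float), kind=kind)
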