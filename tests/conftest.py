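import numpy as np
import pytest

from ctcenterline.core import Grid3D
from ctcenterline.phantom import PhantomSpec, simulate_case
from ctcenterline.preprocess import PreprocessConfig, make_training_pair


@pytest.fixture(scope="session")
def grid():
    """Desk-scale axial grid: 384 x 480 x 192 mm at (4, 5, 6) mm."""
    return Grid3D.centered((96, 96, 32), (4.0, 5.0, 6.0))


@pytest.fixture(scope="session")
def standard_spec():
    """A population-average phantom, 12 mm below the isocenter."""
    return PhantomSpec.from_diameters(243.0, 301.0, table_height_offset=-12.0)


@pytest.fixture(scope="session")
def standard_case(standard_spec, grid):
    return simulate_case(standard_spec, grid, case_id="std")


@pytest.fixture(scope="session")
def small_preprocess():
    return PreprocessConfig(localizer_shape=(24, 16), volume_shape=(32, 24, 16))


@pytest.fixture(scope="session")
def standard_pair(standard_case, small_preprocess):
    return make_training_pair(standard_case.localizer, standard_case.volume,
                              small_preprocess, case_id="std")
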