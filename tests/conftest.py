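import numpy as np
import pytest

from thdtools.interface import SASAParams
from thdtools.structure_io import assign_radii
from thdtools.synthetic_data import make_c3_trimer, make_helix


@pytest.fixture
def helix():
    return assign_radii(make_helix(10))


@pytest.fixture
def trimer():
    st, transforms = make_c3_trimer()
    assign_radii(st)
    return st, transforms


@pytest.fixture
def fast_sasa():
    # coarse quadrature keeps the suite quick; accuracy-sensitive tests set their own
    return SASAParams(points_per_atom=240)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
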