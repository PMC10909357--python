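import warnings

import numpy as np
import pytest

from clockpotts import ModelParams, XorShift128Plus, initialize, make_fixture

# |J| or |K| at the range edge triggers an advisory warning by design;
# silence it for the parameter sets the tests sweep through.
warnings.filterwarnings("ignore", message=r".*lets individual clocks.*")
warnings.filterwarnings("ignore", message=r".*non-positive cell-cell contact.*")


@pytest.fixture
def small_params():
    """A desk-size lattice: 6 cells of 9 sites on 20x20."""
    return ModelParams(J=0.3, K=0.5, dims=(20, 20), N=6, A_target=9, seed=7)


@pytest.fixture
def small_system(small_params):
    state, cells = initialize(small_params, np.random.default_rng(7))
    return state, cells, small_params


@pytest.fixture
def rng():
    return XorShift128Plus(2024)


@pytest.fixture(params=["single_cell_5x5", "two_cell_edge", "two_cell_corner",
                        "four_cell_ring", "checkerboard_8cell", "random_small"])
def any_fixture(request):
    return make_fixture(request.param)
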