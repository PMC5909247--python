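import numpy as np
import pytest

from oddball_stda.forward_model import (
    build_source_grid,
    compute_leadfield,
    standard_montage_1010,
)


@pytest.fixture(scope="session")
def montage():
    return standard_montage_1010()


@pytest.fixture(scope="session")
def grid():
    return build_source_grid(7.8, 10.0)


@pytest.fixture(scope="session")
def coarse_grid():
    return build_source_grid(7.0, 20.0)


@pytest.fixture(scope="session")
def leadfield_car(montage, grid):
    """CAR lead field over all 64 channels (simulation reference)."""
    return compute_leadfield(montage, grid, reference="CAR")


@pytest.fixture(scope="session")
def leadfield_scalp(montage, grid):
    """CAR lead field over the 62 scalp channels (source analysis)."""
    return compute_leadfield(montage, grid, reference="CAR",
                             channels=montage.scalp_labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
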