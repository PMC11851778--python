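import numpy as np
import pytest

from dvcqmri import (
    GeometrySpec,
    build_label_map,
    make_roi_set,
    tissue_params_for,
)


@pytest.fixture(scope="session")
def small_geom():
    """Compact mature geometry (24x24x32) for fast simulation tests."""
    return GeometrySpec.for_maturity("mature", matrix_size=(24, 24, 32), np_radius_vox=6)


@pytest.fixture(scope="session")
def small_label(small_geom):
    return build_label_map(small_geom)


@pytest.fixture(scope="session")
def small_rois(small_label):
    return make_roi_set(small_label, erosion_vox=0)


@pytest.fixture(scope="session")
def healthy_table():
    return tissue_params_for("mature", "healthy", "D0")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
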