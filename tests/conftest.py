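import numpy as np
import pytest

from ppct import (
    DEFAULT_GEOMETRY,
    PatternParams,
    ThicknessGrid,
    select_onh_mask,
)


@pytest.fixture(scope="session")
def geometry():
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def mask(geometry):
    return select_onh_mask(geometry)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def make_grid(values, subject_id="s1", laterality="OD", geometry=DEFAULT_GEOMETRY):
    """Build a ThicknessGrid from a full array or scalar, NaN at ONH cells."""
    m = select_onh_mask(geometry)
    arr = np.full((geometry.n_rows, geometry.n_cols), float("nan"))
    arr[m.analyzed] = np.broadcast_to(
        np.asarray(values, dtype=float), arr.shape
    )[m.analyzed]
    return ThicknessGrid(subject_id, laterality, arr, geometry)


@pytest.fixture()
def constant_grid():
    return make_grid(100.0)


@pytest.fixture()
def random_grid(rng, mask, geometry):
    vals = rng.uniform(60.0, 220.0, size=(geometry.n_rows, geometry.n_cols))
    return make_grid(vals)
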