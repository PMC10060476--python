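import numpy as np
import pytest

from datspect import (
    PhantomSpec,
    make_anatomy,
    painted_template_set,
)
from datspect.voxel_core import Space, VolumetricImage, centered_grid


@pytest.fixture(scope="session")
def spec():
    return PhantomSpec()


@pytest.fixture(scope="session")
def anatomy(spec):
    return make_anatomy(spec)


@pytest.fixture(scope="session")
def masks(anatomy):
    return anatomy[0]


@pytest.fixture(scope="session")
def template_set(spec):
    """Painted noise-free 8-template set (and labels) on the template grid."""
    return painted_template_set(spec)


@pytest.fixture(scope="session")
def normal_template(template_set):
    return template_set[0][0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def small_image(data, voxel_mm=2.0, space=Space.TEMPLATE):
    """Wrap an array in a VolumetricImage on a centered grid."""
    data = np.asarray(data, dtype=np.float64)
    grid = centered_grid(data.shape, voxel_mm, space)
    return VolumetricImage(data, grid.v2w, space)
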