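import numpy as np
import pytest

import gliomaconn as gc


@pytest.fixture(scope="session")
def small_atlas():
    """8-parcel atlas on a 20x20x10 grid (4 parcels per hemisphere)."""
    return gc.make_atlas(8, (20, 20, 10), seed=0)


@pytest.fixture(scope="session")
def desk_atlas():
    """40-parcel atlas at the reduced problem size used by replicate suites."""
    return gc.make_atlas(40, (24, 28, 20), seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_run(data, tr=1.6, voxel_mm=3.0):
    """Wrap an array as a BoldRun on an isotropic grid."""
    data = np.asarray(data, dtype=float)
    affine = np.diag([voxel_mm] * 3 + [1.0])
    return gc.BoldRun(data=data, affine=affine, tr_seconds=tr)


@pytest.fixture
def bold_factory():
    return make_run
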