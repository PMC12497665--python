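import numpy as np
import pytest

from cribromics.grids import GridGeometry, RegionMask, VolumeGrid
from cribromics.phantom import PhantomSpec


@pytest.fixture
def unit_geometry():
    return GridGeometry(spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def tiny_spec():
    """A small but non-trivial cohort spec shared by slow-ish tests."""
    return PhantomSpec(n_cases=20, seed=11)


@pytest.fixture(scope="session")
def tiny_case(tiny_spec):
    from cribromics.phantom import generate_phantom_case

    return generate_phantom_case(tiny_spec, 0)


def make_mask(vox, geometry=None, label="GP3", **kw):
    return RegionMask(
        voxels=np.asarray(vox, dtype=bool),
        geometry=geometry or GridGeometry(spacing=(1.0, 1.0, 1.0)),
        label=label,
        **kw,
    )


def make_volume(data, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    return VolumeGrid(data=np.asarray(data, dtype=float),
                      geometry=GridGeometry(spacing=spacing, origin=origin))
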