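import numpy as np
import pytest

from dbsfem.phantom import (PhantomConfig, Ellipsoid, Slab, build_phantom,
                            make_anisotropy, default_ic_direction_field)
from dbsfem.dielectrics import default_media


@pytest.fixture(scope="session")
def tiny_config() -> PhantomConfig:
    """Small, fast phantom preserving the full region topology."""
    return PhantomConfig(
        domain_extent=(3.0, 3.0, 3.0), voxel_size=0.05,
        stn=Ellipsoid(center=(-0.7, 0.0, -0.5), semi_axes=(0.35, 0.30, 0.20)),
        epn=Ellipsoid(center=(0.7, 0.0, -0.5), semi_axes=(0.25, 0.25, 0.22)),
        thalamus=Slab(bounds=((-1.2, 1.2), (-1.2, 1.2), (0.2, 0.9))),
        ic_sheet=Slab(bounds=((0.2, 1.1), (-1.2, 1.2), (0.0, 0.15))),
        csf_layer=0.15, random_seed=0)


@pytest.fixture(scope="session")
def tiny_phantom(tiny_config):
    return build_phantom(tiny_config)


@pytest.fixture(scope="session")
def tiny_phantom_aniso(tiny_phantom):
    return make_anisotropy(tiny_phantom, default_ic_direction_field, 0.7)


@pytest.fixture(scope="session")
def media():
    return default_media()


@pytest.fixture(scope="session")
def media_resistive():
    return default_media(dispersive=False)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
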