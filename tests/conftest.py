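import numpy as np
import pytest

from ctcontrast import (
    GrayVolume,
    ScanMeta,
    default_annotations,
    default_layout,
    default_uptake_params,
    generate_phantom,
)


@pytest.fixture(scope="session")
def layout160():
    """Desk-scale phantom layout (160^3 voxels at 10 um)."""
    return default_layout()


@pytest.fixture(scope="session")
def params():
    return default_uptake_params(seed=7)


@pytest.fixture(scope="session")
def phantom48(layout160, params):
    """One rendered scan at peak staining time, with ground-truth labels."""
    meta = ScanMeta("AR_SIM", "FORMALIN_BLUGOL", 48.0)
    return generate_phantom(layout160, meta, params)


@pytest.fixture(scope="session")
def annotations(layout160):
    return default_annotations(layout160)


def uniform_volume(value, shape=(4, 32, 32), voxel_size_um=10.0):
    meta = ScanMeta("UNIFORM", "FORMALIN_BLUGOL", 0.0)
    voxels = np.full(shape, value, dtype=np.uint16)
    return GrayVolume(voxels=voxels, voxel_size_um=voxel_size_um, meta=meta)


@pytest.fixture
def make_uniform_volume():
    return uniform_volume
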