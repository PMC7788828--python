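import numpy as np
import pytest

from brainshift.phantom import (
    AcquisitionProtocol,
    CompartmentTruth,
    DiffusionProtocol,
    VoxelGrid,
    build_anatomy,
)


@pytest.fixture(scope="session")
def small_grid() -> VoxelGrid:
    """Coarse desk-scale grid: 0.46 mm isotropic keeps unit tests fast."""
    return VoxelGrid((32, 32, 24), (0.46, 0.46, 0.46))


@pytest.fixture(scope="session")
def small_truth() -> CompartmentTruth:
    """Half-scale compartment volumes that fit the small grid comfortably."""
    return CompartmentTruth.default(csf_volume_mm3=95.0, parenchyma_volume_mm3=920.0)


@pytest.fixture(scope="session")
def small_anatomy(small_grid, small_truth):
    return build_anatomy(small_grid, small_truth, seed=42)


@pytest.fixture(scope="session")
def mge_protocol() -> AcquisitionProtocol:
    return AcquisitionProtocol.mge_default()


@pytest.fixture(scope="session")
def dwi_protocol() -> DiffusionProtocol:
    return DiffusionProtocol.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
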