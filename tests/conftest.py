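import numpy as np
import pytest

from vasquant import Image3D, SegmentVOI, Units, VoxelGrid


@pytest.fixture
def pet_grid() -> VoxelGrid:
    """Clinical-PET-like grid (small in-plane for fast tests)."""
    return VoxelGrid((24, 24, 16), (4.0, 4.0, 4.0))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170811)


@pytest.fixture
def random_image(pet_grid, rng) -> Image3D:
    vals = rng.gamma(2.0, 1.0, size=pet_grid.shape)
    return Image3D(pet_grid, vals, Units.SUV)


@pytest.fixture
def box_voi(pet_grid) -> SegmentVOI:
    mask = np.zeros(pet_grid.shape, dtype=bool)
    mask[8:16, 8:16, 4:12] = True
    return SegmentVOI("aortic_arch", pet_grid, mask)
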