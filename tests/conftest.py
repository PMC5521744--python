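import numpy as np
import pytest

from biofilmct import (LabelVolume, PhantomSpec, VolumeImage,
                       generate_grain_pack, grow_biofilm)
from biofilmct.core import BIOFILM, LIQUID, OUTSIDE, SOLID


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Desk-size phantom used across tests (64^3, 20-voxel grains)."""
    return PhantomSpec(column_diameter_vox=64, column_length_vox=64,
                       grain_diameter_vox=20.0, target_porosity=0.42,
                       biofilm_fraction=0.12, seed=11)


@pytest.fixture(scope="session")
def packed_labels(small_spec) -> LabelVolume:
    return generate_grain_pack(small_spec)


@pytest.fixture(scope="session")
def biofilm_labels(small_spec, packed_labels) -> LabelVolume:
    return grow_biofilm(packed_labels, small_spec)


@pytest.fixture()
def hand_labels() -> LabelVolume:
    """2x2x2 in-column fixture: 4 solid, 3 liquid, 1 biofilm."""
    codes = np.array([[[SOLID, SOLID], [SOLID, SOLID]],
                      [[LIQUID, LIQUID], [LIQUID, BIOFILM]]], dtype=np.uint8)
    return LabelVolume(codes, (1.0, 1.0, 1.0))


def disk_volume(n: int = 64, radius: float = 20.0, mu: float = 0.02,
                nz: int = 1) -> VolumeImage:
    yy, xx = np.mgrid[:n, :n]
    c = (n - 1) / 2.0
    disk = (np.hypot(yy - c, xx - c) <= radius).astype(float) * mu
    return VolumeImage(np.broadcast_to(disk, (nz, n, n)).copy(), (1.0, 1.0, 1.0))
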