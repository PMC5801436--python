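import numpy as np
import pytest

from megfem.spheremesh import (
    CompartmentSpec,
    HexMesh,
    VoxelSegmentation,
    build_hex_mesh,
    voxelize_sphere,
)


def make_box_mesh(
    shape=(2, 2, 2),
    h=0.01,
    sigma=1.0,
    labels=None,
    compartments=None,
) -> HexMesh:
    """Rectangular block of hexahedra, optionally with per-voxel labels."""
    if labels is None:
        labels = np.ones(shape, dtype=np.int16)
    if compartments is None:
        nlab = int(labels.max())
        sig = np.atleast_1d(sigma)
        if len(sig) == 1:
            sig = np.repeat(sig, nlab)
        compartments = tuple(
            CompartmentSpec(f"c{k}", 0.01 * (k + 1), float(sig[k])) for k in range(nlab)
        )
    seg = VoxelSegmentation(origin=np.zeros(3), voxel_size=h, labels=labels)
    return build_hex_mesh(seg, compartments)


@pytest.fixture
def unit_element():
    """A single 1 cm cube with sigma = 0.8."""
    return make_box_mesh((1, 1, 1), sigma=0.8)


@pytest.fixture
def cube2_mesh():
    """2 x 2 x 2 uniform block, sigma = 0.7."""
    return make_box_mesh((2, 2, 2), sigma=0.7)


@pytest.fixture
def grid3_mesh():
    """3 x 3 x 3 uniform block, sigma = 1."""
    return make_box_mesh((3, 3, 3), sigma=1.0)


@pytest.fixture(scope="session")
def tiny_two_layer():
    """Small two-compartment sphere (brain 11 mm / skull-like shell 19 mm)
    at 4 mm: 432 elements, enough structure for subtraction-source tests."""
    comps = (
        CompartmentSpec("brain", 0.011, 0.33),
        CompartmentSpec("skull", 0.019, 0.01),
    )
    return build_hex_mesh(voxelize_sphere(comps, 4e-3), comps)


@pytest.fixture(scope="session")
def tiny_four_layer():
    """Miniature four-layer sphere (9/13/17/21 mm at 4 mm resolution) with
    the standard conductivities: the smallest mesh exhibiting all interface
    contrasts (624 elements)."""
    comps = (
        CompartmentSpec("brain", 0.009, 0.33),
        CompartmentSpec("csf", 0.013, 1.79),
        CompartmentSpec("skull", 0.017, 0.01),
        CompartmentSpec("skin", 0.021, 0.43),
    )
    return build_hex_mesh(voxelize_sphere(comps, 4e-3), comps)
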