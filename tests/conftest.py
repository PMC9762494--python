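"""Shared small fixtures: analytic phantoms and rendered stacks."""

import numpy as np
import pytest

from eecm import (
    NoiseSpec,
    PhantomSpec,
    generate_channel_phantom,
    generate_fiber_phantom,
    generate_plate_phantom,
    render_grayscale,
)
from eecm.volumes import BinaryMicrostructure


@pytest.fixture(scope="session")
def channel32():
    """Straight circular pore channel along z: 32^3, 1 um voxels, r = 8 um."""
    return generate_channel_phantom((32, 32, 32), 1.0, 8.0, axis="z")


@pytest.fixture(scope="session")
def slit32():
    """Planar pore slit normal to z: 32^3, 1 um voxels, gap 8 um."""
    return generate_plate_phantom((32, 32, 32), 1.0, 8.0, normal_axis="z")


@pytest.fixture(scope="session")
def fiber_phantom32():
    """Small endoneurium-like phantom with its generation report."""
    spec = PhantomSpec(shape=(32, 32, 32), seed=7)
    return generate_fiber_phantom(spec)


@pytest.fixture(scope="session")
def fiber_phantom24():
    """Smallest useful endoneurium-like phantom, for the slow voxel-FEM tests."""
    spec = PhantomSpec(shape=(24, 24, 24), seed=7)
    return generate_fiber_phantom(spec)


@pytest.fixture(scope="session")
def noiseless_rendering(fiber_phantom32):
    """Exact two-level grayscale rendering of a known binary."""
    binary, _ = fiber_phantom32
    return binary, render_grayscale(
        binary, NoiseSpec(blur_sigma=0.0, noise_sd=0.0, fg_level=200, bg_level=50)
    )


@pytest.fixture()
def half_slab():
    """16^3 volume whose lower half (z) is solid: porosity exactly 0.5."""
    solid = np.zeros((16, 16, 16), dtype=bool)
    solid[:8] = True
    return BinaryMicrostructure(solid, 1.0)
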