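"""Shared fixtures: small phantoms built programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from coreshell.phantom import PhantomSpec, render_geometry_phantom
from coreshell.stacks import BinaryMask3D


@pytest.fixture(scope="session")
def small_cap_spec() -> PhantomSpec:
    """Coarse cap phantom (0.9 µm voxels) that is fast to analyze."""
    return PhantomSpec(
        grid_shape=(96, 96, 96),
        spacing=(0.9, 0.9, 0.9),
        core_radius=20.0,
        shell_thickness=12.0,
        coverage_fraction=0.912,
        cap_axis=(0.0, 0.0, -1.0),
    )


@pytest.fixture(scope="session")
def small_full_spec() -> PhantomSpec:
    return PhantomSpec(
        grid_shape=(96, 96, 96),
        spacing=(0.9, 0.9, 0.9),
        core_radius=20.0,
        shell_thickness=12.0,
        coverage_fraction=1.0,
    )


@pytest.fixture(scope="session")
def small_geometry(small_full_spec):
    return render_geometry_phantom(small_full_spec)


def make_ball_mask(shape, spacing, center, radius) -> BinaryMask3D:
    """Digital ball: voxels whose centers lie within ``radius`` of ``center``."""
    offs = [np.arange(n) * s - c for n, s, c in zip(shape, spacing, center)]
    d2 = (
        offs[0][:, None, None] ** 2
        + offs[1][None, :, None] ** 2
        + offs[2][None, None, :] ** 2
    )
    return BinaryMask3D(d2 <= radius**2, spacing)
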