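"""Reference phantom fixtures at the study's mean spheroid geometry.

The default phantom parameters reproduce the mean geometry of the imaged
core-shell OVCAR-8 spheroid population: core radius 34.3 µm, shell
thickness 23.2 µm, shell coverage 91.2%, outer (line-analysis) radius
64.0 µm, 293 cells at a 2:1 shell:core seeding ratio (37 core + 256 shell
nuclei), shell-channel voxel fractions 70.2% in the shell and 7.6% in the
core.  Grids are sized to hold the spheroid at the acquisition voxel
spacing with the required margin.
"""

from __future__ import annotations

import math

from .phantom import PhantomSpec

# reference (population-mean) geometry, µm / % unless noted
CORE_RADIUS = 34.3
SHELL_THICKNESS = 23.2
OUTER_RADIUS = 64.0
COVERAGE_FRACTION = 0.912
SHELL_LABEL_PURITY = 0.702
CORE_CONTAMINATION = 0.076
N_CORE_NUCLEI = 37
N_SHELL_NUCLEI = 256

ISO_SPACING = 0.45  # µm, isotropic analysis voxel
ACQ_SPACING = (0.4393, 0.4393, 0.9)  # µm, acquisition voxel


def _grid_for(outer_radius: float, spacing) -> tuple[int, int, int]:
    """Smallest even grid holding the spheroid with a 3-voxel margin."""
    shape = []
    for s in spacing:
        n = int(math.ceil(2.0 * (outer_radius + 3.0 * s) / s)) + 1
        shape.append(n + n % 2)
    return tuple(shape)


def coverage_spec(coverage: float = COVERAGE_FRACTION) -> PhantomSpec:
    """Cap phantom for shell-coverage recovery (cap axis −z)."""
    outer = CORE_RADIUS + SHELL_THICKNESS
    return PhantomSpec(
        grid_shape=_grid_for(outer, (ISO_SPACING,) * 3),
        spacing=(ISO_SPACING,) * 3,
        core_radius=CORE_RADIUS,
        shell_thickness=SHELL_THICKNESS,
        coverage_fraction=coverage,
        cap_axis=(0.0, 0.0, -1.0),
    )


def geometry_spec() -> PhantomSpec:
    """Full-coverage phantom for shell-thickness / core-radius recovery."""
    return coverage_spec(coverage=1.0)


def ball_spec(radius: float = OUTER_RADIUS) -> PhantomSpec:
    """Plain ball (no shell) for radius recovery; here the 'core' is the
    whole spheroid."""
    return PhantomSpec(
        grid_shape=_grid_for(radius, (ISO_SPACING,) * 3),
        spacing=(ISO_SPACING,) * 3,
        core_radius=radius,
        shell_thickness=0.0,
        coverage_fraction=1.0,
    )


def content_spec(seed: int = 0) -> PhantomSpec:
    """Stochastic phantom for compartment-content recovery."""
    spec = geometry_spec()
    return spec.model_copy(
        update={
            "shell_label_purity": SHELL_LABEL_PURITY,
            "core_contamination": CORE_CONTAMINATION,
            "rng_seed": seed,
        }
    )


def cell_count_spec(seed: int = 0) -> PhantomSpec:
    """Image phantom with the reference cell count, at acquisition spacing."""
    outer = CORE_RADIUS + SHELL_THICKNESS
    return PhantomSpec(
        grid_shape=_grid_for(outer, ACQ_SPACING),
        spacing=ACQ_SPACING,
        core_radius=CORE_RADIUS,
        shell_thickness=SHELL_THICKNESS,
        coverage_fraction=1.0,
        n_core_nuclei=N_CORE_NUCLEI,
        n_shell_nuclei=N_SHELL_NUCLEI,
        shell_label_purity=SHELL_LABEL_PURITY,
        core_contamination=0.0,
        rng_seed=seed,
    )
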