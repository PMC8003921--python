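"""Parameter-recovery experiments on reference phantoms.

Each runner builds a phantom at the reference (population-mean) geometry,
runs the relevant slice of the analysis pipeline from scratch, and returns
the recovered quantities next to the constructed truth.  These are the
experiments behind the package's validation claims; the acceptance tests
and ``scripts/acceptance.py`` both call them.
"""

from __future__ import annotations

import numpy as np

from . import presets
from .compartments import compartmentalize
from .config import PipelineConfig
from .morphometry import farred_voxel_ratio, measure, estimate_cell_count
from .nuclei import median_nucleus_volume, separate_nuclei
from .phantom import render_content_phantom, render_geometry_phantom, render_image_phantom
from .radial_lines import aggregate_lines, angular_trend, trace_lines
from .segmentation import (
    adaptive_threshold,
    gaussian_smooth,
    interpolate_isotropic,
    morphological_cleanup,
)
from .stacks import BinaryMask3D


def mask_centroid(mask: BinaryMask3D) -> np.ndarray:
    """Unweighted physical centroid of a mask (µm)."""
    idx = np.argwhere(mask.data)
    return idx.mean(axis=0) * np.asarray(mask.spacing)


def run_coverage_recovery(n_points: int = 5000) -> dict:
    """Shell-coverage recovery on the reference cap phantom."""
    spec = presets.coverage_spec()
    whole, shell, _ = render_geometry_phantom(spec)
    center = mask_centroid(whole)
    lines = trace_lines(whole, shell, center, n_points)
    summary = aggregate_lines(lines)
    return {
        "coverage_percent": summary["coverage_percent"],
        "true_coverage_percent": 100.0 * spec.coverage_fraction,
        "n_lines": n_points,
        "polar_trend": angular_trend(lines, "polar"),
        "azimuth_trend": angular_trend(lines, "azimuth"),
    }


def run_geometry_recovery(n_points: int = 5000) -> dict:
    """Shell-thickness and core-radius recovery on the full-coverage phantom."""
    spec = presets.geometry_spec()
    whole, shell, _ = render_geometry_phantom(spec)
    center = mask_centroid(whole)
    lines = trace_lines(whole, shell, center, n_points)
    summary = aggregate_lines(lines)
    return {
        "mean_shell_thickness_um": summary["mean_shell_thickness_um"],
        "mean_core_radius_um": summary["mean_core_radius_um"],
        "mean_radius_um": summary["mean_radius_um"],
        "true_shell_thickness_um": spec.shell_thickness,
        "true_core_radius_um": spec.core_radius,
        "true_outer_radius_um": spec.outer_radius,
        "n_lines": n_points,
    }


def run_radius_recovery(n_points: int = 5000) -> dict:
    """Spheroid-radius recovery on a ball of the reference outer radius,
    plus the volume-based equivalent radius for internal consistency."""
    spec = presets.ball_spec()
    whole, _, _ = render_geometry_phantom(spec)
    center = mask_centroid(whole)
    farred_empty = BinaryMask3D(np.zeros(whole.shape, bool), whole.spacing)
    lines = trace_lines(whole, farred_empty, center, n_points)
    summary = aggregate_lines(lines)
    morpho = measure(whole)
    return {
        "mean_radius_um": summary["mean_radius_um"],
        "equivalent_radius_um": morpho.equivalent_diameter_um / 2.0,
        "volume_um3": morpho.volume_um3,
        "true_radius_um": spec.core_radius,
        "n_lines": n_points,
    }


def run_content_recovery(seed: int = 0, n_points: int = 5000) -> dict:
    """Compartment-content recovery on the stochastic label phantom.

    The compartment geometry is derived from the volume-filtered shell
    mask (isolated label noise cannot outline the core); the content
    fractions are measured with the raw label field inside the
    reconstructed compartments.
    """
    config = PipelineConfig()
    spec = presets.content_spec(seed)
    whole, farred_raw, _, truth = render_content_phantom(spec)
    farred_geom = morphological_cleanup(
        farred_raw, config.min_object_volume, fill_holes=False
    )
    center = mask_centroid(whole)
    lines = trace_lines(whole, farred_geom, center, n_points)
    core_mask, shell_mask = compartmentalize(
        lines, whole, config.shadow_closing_radius
    )
    return {
        "core_farred_percent": 100.0 * farred_voxel_ratio(farred_raw, core_mask),
        "shell_farred_percent": 100.0 * farred_voxel_ratio(farred_raw, shell_mask),
        "true_core_percent": 100.0 * truth.core_label_fraction,
        "true_shell_percent": 100.0 * truth.shell_label_fraction,
        "nominal_core_percent": 100.0 * spec.core_contamination,
        "nominal_shell_percent": 100.0 * spec.shell_label_purity,
        "core_voxels": int(core_mask.data.sum()),
        "shell_voxels": int(shell_mask.data.sum()),
    }


def run_cell_count_recovery(seed: int = 0) -> dict:
    """Cell-count recovery on a noise-free image phantom with the
    reference nucleus count, through segmentation and two-pass watershed."""
    config = PipelineConfig()
    spec = presets.cell_count_spec(seed)
    stack, truth = render_image_phantom(spec)
    iso = interpolate_isotropic(stack, config.target_z_spacing)
    smooth = gaussian_smooth(iso, config.smooth_sigma)
    dapi_raw = adaptive_threshold(
        smooth.nuclear, smooth.spacing, config.neighborhood_divisor, config.sensitivity
    )
    dapi_mask = morphological_cleanup(
        dapi_raw, config.min_object_volume, fill_holes=True
    )
    labels = separate_nuclei(
        dapi_mask, h=config.h_minima_depth, refine_fraction=config.refine_fraction
    )
    med = median_nucleus_volume(labels)
    estimate, rounded = estimate_cell_count(dapi_mask, med)
    true_n = truth.n_core_nuclei + truth.n_shell_nuclei
    return {
        "cell_count_estimate": estimate,
        "cell_count_rounded": rounded,
        "true_cell_count": true_n,
        "n_watershed_labels": labels.n_labels,
        "median_nucleus_volume_um3": med,
        "true_median_nucleus_volume_um3": float(np.median(truth.nucleus_volumes)),
    }
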