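"""End-to-end pipeline: raw stack → per-spheroid report.

Stage order: isotropic interpolation → Gaussian smoothing → adaptive
thresholding per channel → morphological cleanup → two-pass watershed on
the nuclear mask → whole-volume morphometry → center-to-surface line
analysis → core/shell compartmentalization and content.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .compartments import CompartmentContent, compartment_content, compartmentalize
from .config import PipelineConfig
from .morphometry import (
    Morphometry,
    estimate_cell_count,
    farred_voxel_ratio,
    measure,
    whole_volume_mask,
)
from .nuclei import median_nucleus_volume, nucleus_table, separate_nuclei
from .radial_lines import (
    aggregate_lines,
    angular_trend,
    concentric_layer_ratios,
    find_core_center,
    lines_table,
    trace_lines,
)
from .segmentation import (
    adaptive_threshold,
    gaussian_smooth,
    interpolate_isotropic,
    morphological_cleanup,
)
from .stacks import BinaryMask3D, LabelVolume, VoxelStack


@dataclass
class SpheroidReport:
    """Everything the pipeline measured for one stack."""

    morphometry: Morphometry
    cell_count_estimate: float
    cell_count_rounded: int
    farred_voxel_ratio: float
    median_nucleus_volume: float
    line_summary: dict
    compartments: CompartmentContent
    core_center_um: tuple[float, float, float]
    lines: pd.DataFrame
    layers: pd.DataFrame
    azimuth_trend: pd.DataFrame
    polar_trend: pd.DataFrame
    nuclei: pd.DataFrame
    dapi_mask: BinaryMask3D
    farred_mask: BinaryMask3D
    whole_mask: BinaryMask3D
    core_mask: BinaryMask3D
    shell_mask: BinaryMask3D
    labels: LabelVolume
    config: dict = field(default_factory=dict)
    config_hash: str = ""
    version: str = __version__
    timings_s: dict = field(default_factory=dict)

    def summary(self) -> dict:
        """Flat JSON-serializable summary of the scalar outputs."""
        return {
            "version": self.version,
            "config_hash": self.config_hash,
            "config": self.config,
            "core_center_um": list(self.core_center_um),
            "morphometry": self.morphometry.to_dict(),
            "cell_count_estimate": self.cell_count_estimate,
            "cell_count_rounded": self.cell_count_rounded,
            "farred_voxel_ratio": self.farred_voxel_ratio,
            "median_nucleus_volume_um3": self.median_nucleus_volume,
            "line_summary": self.line_summary,
            "compartments": self.compartments.to_dict(),
            "timings_s": self.timings_s,
        }


def run_pipeline(stack: VoxelStack, config: PipelineConfig | None = None) -> SpheroidReport:
    """Run every analysis stage on a two-channel stack."""
    config = config or PipelineConfig()
    timings: dict[str, float] = {}

    def tick(name: str, t0: float) -> float:
        timings[name] = round(time.perf_counter() - t0, 3)
        return time.perf_counter()

    t0 = time.perf_counter()
    iso = interpolate_isotropic(stack, config.target_z_spacing)
    t0 = tick("interpolate", t0)
    smooth = gaussian_smooth(iso, config.smooth_sigma)
    t0 = tick("smooth", t0)

    dapi_raw = adaptive_threshold(
        smooth.nuclear, smooth.spacing, config.neighborhood_divisor, config.sensitivity
    )
    farred_raw = adaptive_threshold(
        smooth.shell, smooth.spacing, config.neighborhood_divisor, config.sensitivity
    )
    t0 = tick("threshold", t0)
    dapi_mask = morphological_cleanup(
        dapi_raw, config.min_object_volume, fill_holes=config.dapi_fill_holes
    )
    farred_mask = morphological_cleanup(
        farred_raw, config.min_object_volume, fill_holes=config.farred_fill_holes
    )
    t0 = tick("cleanup", t0)

    labels = separate_nuclei(
        dapi_mask, h=config.h_minima_depth, refine_fraction=config.refine_fraction
    )
    med_volume = median_nucleus_volume(labels)
    nuclei_df = nucleus_table(labels)
    t0 = tick("watershed", t0)

    whole = whole_volume_mask(dapi_mask, farred_mask, config.whole_closing_radius)
    morpho = measure(whole)
    count_est, count_round = estimate_cell_count(dapi_mask, med_volume)
    fr_ratio = farred_voxel_ratio(farred_mask, whole)
    t0 = tick("morphometry", t0)

    center = find_core_center(smooth.nuclear, dapi_mask, farred_mask)
    layers = concentric_layer_ratios(whole, farred_mask, center, config.layer_width)
    lines = trace_lines(whole, farred_mask, center, config.n_surface_points)
    line_summary = aggregate_lines(lines)
    az_trend = angular_trend(lines, "azimuth", config.azimuth_bin)
    po_trend = angular_trend(lines, "polar", config.polar_bin)
    t0 = tick("radial_lines", t0)

    core_mask, shell_mask = compartmentalize(lines, whole, config.shadow_closing_radius)
    content = compartment_content(core_mask, shell_mask, farred_mask, dapi_mask, med_volume)
    tick("compartments", t0)

    return SpheroidReport(
        morphometry=morpho,
        cell_count_estimate=count_est,
        cell_count_rounded=count_round,
        farred_voxel_ratio=fr_ratio,
        median_nucleus_volume=med_volume,
        line_summary=line_summary,
        compartments=content,
        core_center_um=tuple(float(c) for c in center),
        lines=lines_table(lines),
        layers=layers,
        azimuth_trend=az_trend,
        polar_trend=po_trend,
        nuclei=nuclei_df,
        dapi_mask=dapi_mask,
        farred_mask=farred_mask,
        whole_mask=whole,
        core_mask=core_mask,
        shell_mask=shell_mask,
        labels=labels,
        config=config.model_dump(),
        config_hash=config.config_hash(),
        timings_s=timings,
    )
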