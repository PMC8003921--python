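"""Synthetic core-shell spheroid phantoms with machine-readable ground truth.

The generator emulates the data product of two-channel confocal imaging of
a single scaffold-free core-shell multicellular tumor spheroid (MCTS) per
field of view: a roughly spherical core of unlabeled nuclei surrounded by a
shell of nuclei embedded in shell-channel-positive cell volume.  Two levels
of realism are provided:

* **geometry phantoms** — exact, noise-free binary masks (whole spheroid,
  shell channel, true core) whose analytic ground truth is known by
  construction; used wherever exactness matters;
* **image phantoms** — intensity stacks with ellipsoidal nuclei, optional
  Gaussian blur, background offset, and noise, sampled at (possibly
  anisotropic) acquisition spacing.

Shell coverage is imposed as a single polar spherical cap of missing shell
aligned to ``cap_axis`` (default −z, the well bottom), which gives the cap
a closed-form half angle for any requested coverage fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .stacks import BinaryMask3D, VoxelStack


class PhantomError(ValueError):
    """Raised when a phantom cannot be generated from its spec."""


class PhantomSpec(BaseModel):
    """Parameters of one synthetic core-shell spheroid.

    All lengths are in micrometres.  ``coverage_fraction`` is the fraction
    of ray directions (solid angle) covered by shell; the complement is a
    single spherical cap around ``cap_axis``.
    """

    grid_shape: tuple[int, int, int] = (128, 128, 128)
    spacing: tuple[float, float, float] = (0.45, 0.45, 0.45)
    center: tuple[float, float, float] | None = None

    core_radius: float = 34.3
    shell_thickness: float = 23.2
    coverage_fraction: float = Field(default=1.0, ge=0.0, le=1.0)
    cap_axis: tuple[float, float, float] = (0.0, 0.0, -1.0)

    n_core_nuclei: int = Field(default=0, ge=0)
    n_shell_nuclei: int = Field(default=0, ge=0)
    nucleus_radius_mean: float = 4.0
    nucleus_radius_sd: float = 0.3
    # minimum surface clearance between nuclei; keep >= the largest voxel
    # dimension so generated gaps are representable at the sampling
    # resolution (sub-voxel gaps would alias into merged objects)
    nucleus_clearance: float = 1.0

    shell_label_purity: float = Field(default=1.0, ge=0.0, le=1.0)
    core_contamination: float = Field(default=0.0, ge=0.0, le=1.0)

    psf_sigma: tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_model: Literal["none", "gaussian", "poisson"] = "none"
    noise_sd: float = Field(default=0.0, ge=0.0)
    noise_scale: float = Field(default=100.0, gt=0.0)
    background_offset: float = 0.05

    rng_seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "PhantomSpec":
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        if any(n < 2 for n in self.grid_shape):
            raise ValueError("grid_shape axes must be >= 2")
        if self.core_radius <= 0:
            raise ValueError("core_radius must be > 0")
        if self.shell_thickness < 0:
            raise ValueError("shell_thickness must be >= 0")
        if not any(abs(c) > 0 for c in self.cap_axis):
            raise ValueError("cap_axis must be a nonzero vector")
        if self.center is None:
            object.__setattr__(
                self,
                "center",
                tuple((n - 1) * s / 2 for n, s in zip(self.grid_shape, self.spacing)),
            )
        outer = self.core_radius + self.shell_thickness
        for axis in range(3):
            n, s, c = self.grid_shape[axis], self.spacing[axis], self.center[axis]
            if c - outer < 2 * s or c + outer > (n - 1) * s - 2 * s:
                raise PhantomError(
                    f"spheroid (outer radius {outer:.1f} µm) does not fit grid axis "
                    f"{axis} ({n} voxels at {s} µm) with a 2-voxel margin"
                )
        return self

    @property
    def outer_radius(self) -> float:
        return self.core_radius + self.shell_thickness

    @property
    def cap_unit(self) -> np.ndarray:
        v = np.asarray(self.cap_axis, dtype=float)
        return v / np.linalg.norm(v)


@dataclass
class GroundTruth:
    """True values a phantom was built from, for parameter-recovery tests."""

    core_radius: float
    shell_thickness: float
    outer_radius: float
    coverage_percent: float
    center: tuple[float, float, float]
    n_core_nuclei: int = 0
    n_shell_nuclei: int = 0
    shell_label_fraction: float = 1.0
    core_label_fraction: float = 0.0
    nucleus_centers: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    nucleus_semi_axes: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    nucleus_volumes: np.ndarray = field(default_factory=lambda: np.zeros(0))
    nucleus_compartment: np.ndarray = field(default_factory=lambda: np.zeros(0, int))

    def to_dict(self) -> dict:
        d = {
            "core_radius": self.core_radius,
            "shell_thickness": self.shell_thickness,
            "outer_radius": self.outer_radius,
            "coverage_percent": self.coverage_percent,
            "center": list(self.center),
            "n_core_nuclei": self.n_core_nuclei,
            "n_shell_nuclei": self.n_shell_nuclei,
            "shell_label_fraction": self.shell_label_fraction,
            "core_label_fraction": self.core_label_fraction,
            "nucleus_centers": self.nucleus_centers.tolist(),
            "nucleus_semi_axes": self.nucleus_semi_axes.tolist(),
            "nucleus_volumes": self.nucleus_volumes.tolist(),
            "nucleus_compartment": self.nucleus_compartment.tolist(),
        }
        return d


def cap_half_angle(coverage_fraction: float) -> float:
    """Half angle α (radians) of the uncovered polar cap.

    The spherical-cap solid-angle fraction ``(1 - cos α) / 2`` equals the
    uncovered fraction ``1 - coverage_fraction``, hence
    ``α = arccos(2·coverage_fraction − 1)``.
    """
    if not 0.0 <= coverage_fraction <= 1.0:
        raise ValueError(f"coverage_fraction must be in [0, 1], got {coverage_fraction}")
    return float(math.acos(2.0 * coverage_fraction - 1.0))


def _radial_grid(spec: PhantomSpec):
    """Distance-to-center grid (µm) and per-axis offsets, broadcastable."""
    offs = [
        (np.arange(n) * s - c).astype(np.float64)
        for n, s, c in zip(spec.grid_shape, spec.spacing, spec.center)
    ]
    dx = offs[0][:, None, None]
    dy = offs[1][None, :, None]
    dz = offs[2][None, None, :]
    dist = np.sqrt(dx * dx + dy * dy + dz * dz)
    return dist, (dx, dy, dz)


def _covered_directions(spec: PhantomSpec, dist, offsets) -> np.ndarray:
    """Boolean grid: voxel direction lies outside the uncovered cap."""
    alpha = cap_half_angle(spec.coverage_fraction)
    if alpha == 0.0:
        return np.ones(spec.grid_shape, dtype=bool)
    if spec.coverage_fraction == 0.0:
        return np.zeros(spec.grid_shape, dtype=bool)
    ux, uy, uz = spec.cap_unit
    dx, dy, dz = offsets
    dot = dx * ux + dy * uy + dz * uz
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_angle = np.where(dist > 0, dot / np.where(dist > 0, dist, 1.0), 1.0)
    return cos_angle < math.cos(alpha)


def render_geometry_phantom(
    spec: PhantomSpec,
) -> tuple[BinaryMask3D, BinaryMask3D, BinaryMask3D]:
    """Noise-free binary phantom: (whole mask, shell-channel mask, true core).

    The whole mask is the ball of radius ``core_radius + shell_thickness``;
    the shell mask is the annulus ``(core_radius, outer]`` restricted to
    directions outside the uncovered cap.  Deterministic for a fixed spec.
    """
    dist, offsets = _radial_grid(spec)
    whole = dist <= spec.outer_radius
    core = dist <= spec.core_radius
    if spec.shell_thickness == 0:
        shell = np.zeros(spec.grid_shape, dtype=bool)
    else:
        shell = whole & ~core & _covered_directions(spec, dist, offsets)
    sp = spec.spacing
    return BinaryMask3D(whole, sp), BinaryMask3D(shell, sp), BinaryMask3D(core, sp)


def render_content_phantom(
    spec: PhantomSpec,
) -> tuple[BinaryMask3D, BinaryMask3D, BinaryMask3D, GroundTruth]:
    """Geometry phantom with stochastic per-voxel shell-channel labels.

    Shell-region voxels (within the covered solid angle) are labelled
    positive independently with probability ``shell_label_purity``; true-core
    voxels with probability ``core_contamination``.  Returns
    ``(whole, farred_labels, true_core, truth)`` where the recorded label
    fractions are the realized (not nominal) ones.
    """
    whole, shell, core = render_geometry_phantom(spec)
    rng = np.random.default_rng(spec.rng_seed)
    farred = np.zeros(spec.grid_shape, dtype=bool)
    n_shell = int(shell.data.sum())
    n_core = int(core.data.sum())
    if n_shell:
        farred[shell.data] = rng.random(n_shell) < spec.shell_label_purity
    if n_core and spec.core_contamination > 0:
        farred[core.data] = rng.random(n_core) < spec.core_contamination
    truth = GroundTruth(
        core_radius=spec.core_radius,
        shell_thickness=spec.shell_thickness,
        outer_radius=spec.outer_radius,
        coverage_percent=100.0 * spec.coverage_fraction,
        center=spec.center,
        shell_label_fraction=float(farred[shell.data].mean()) if n_shell else 0.0,
        core_label_fraction=float(farred[core.data].mean()) if n_core else 0.0,
    )
    return whole, BinaryMask3D(farred, spec.spacing), core, truth


def _draw_semi_axes(rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    """Three ellipsoid semi-axes from a truncated normal (±3 sd, floor 0.5 µm)."""
    mean, sd = spec.nucleus_radius_mean, spec.nucleus_radius_sd
    axes = rng.normal(mean, sd, size=3)
    axes = np.clip(axes, max(0.5, mean - 3 * sd), mean + 3 * sd)
    return axes


def _place_nuclei(
    rng: np.random.Generator,
    spec: PhantomSpec,
    n: int,
    region: str,
    placed_centers: list[np.ndarray],
    placed_radii: list[float],
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Rejection-sample ``n`` non-overlapping ellipsoids in core or shell."""
    alpha = cap_half_angle(spec.coverage_fraction)
    cos_alpha = math.cos(alpha)
    cap = spec.cap_unit
    center = np.asarray(spec.center)
    gap = spec.nucleus_clearance  # µm clearance between bounding spheres
    centers, semi_axes = [], []
    max_attempts = 200 * max(n, 1) + 1000
    attempts = 0
    while len(centers) < n:
        if attempts >= max_attempts:
            raise PhantomError(
                f"could not place {n} non-overlapping nuclei in the {region} "
                f"after {max_attempts} attempts (placed {len(centers)})"
            )
        attempts += 1
        axes = _draw_semi_axes(rng, spec)
        r_bound = float(axes.max())
        u = rng.standard_normal(3)
        u /= np.linalg.norm(u)
        if region == "core":
            r_max = spec.core_radius - r_bound
            if r_max <= 0:
                continue  # this draw does not fit; retry within the budget
            radial = r_max * rng.random() ** (1 / 3)
        else:
            if spec.coverage_fraction > 0 and float(u @ cap) >= cos_alpha:
                continue  # direction inside the uncovered cap
            a = spec.core_radius + r_bound
            b = spec.outer_radius - r_bound
            if b <= a:
                continue  # this draw does not fit; retry within the budget
            radial = (rng.random() * (b**3 - a**3) + a**3) ** (1 / 3)
        pos = center + radial * u
        ok = True
        for c_other, r_other in zip(placed_centers, placed_radii):
            if np.linalg.norm(pos - c_other) < r_bound + r_other + gap:
                ok = False
                break
        if ok:
            centers.append(pos)
            semi_axes.append(axes)
            placed_centers.append(pos)
            placed_radii.append(r_bound)
    return centers, semi_axes


def _rasterize_ellipsoid(
    grid: np.ndarray, spacing, center: np.ndarray, axes: np.ndarray
) -> None:
    """Set voxels with center inside the axis-aligned ellipsoid to 1.0."""
    lo = [max(0, int(math.floor((center[a] - axes[a]) / spacing[a]))) for a in range(3)]
    hi = [
        min(grid.shape[a], int(math.ceil((center[a] + axes[a]) / spacing[a])) + 1)
        for a in range(3)
    ]
    if any(lo[a] >= hi[a] for a in range(3)):
        return
    coords = [
        (np.arange(lo[a], hi[a]) * spacing[a] - center[a]) / axes[a] for a in range(3)
    ]
    q = (
        coords[0][:, None, None] ** 2
        + coords[1][None, :, None] ** 2
        + coords[2][None, None, :] ** 2
    )
    sub = grid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    sub[q <= 1.0] = 1.0


def render_image_phantom(spec: PhantomSpec) -> tuple[VoxelStack, GroundTruth]:
    """Intensity phantom: ellipsoidal nuclei plus a labelled shell volume.

    Nuclear channel holds ``n_core_nuclei`` non-overlapping nuclei inside the
    core and ``n_shell_nuclei`` inside the covered shell.  The shell channel
    is the shell cell volume labelled at ``shell_label_purity`` plus core
    voxels at ``core_contamination``.  Both channels get a fixed background
    offset, optional axis-wise Gaussian blur (``psf_sigma`` µm), and the
    requested noise model.  Bit-identical for identical spec (incl. seed).
    """
    from scipy import ndimage

    # separate stream from the voxel-label draw in render_content_phantom
    rng = np.random.default_rng([spec.rng_seed, 1])
    whole, farred_mask, core_mask, truth = render_content_phantom(spec)

    placed_centers: list[np.ndarray] = []
    placed_radii: list[float] = []
    core_centers, core_axes = _place_nuclei(
        rng, spec, spec.n_core_nuclei, "core", placed_centers, placed_radii
    )
    shell_centers, shell_axes = _place_nuclei(
        rng, spec, spec.n_shell_nuclei, "shell", placed_centers, placed_radii
    )

    nuclear = np.zeros(spec.grid_shape, dtype=np.float64)
    all_centers = core_centers + shell_centers
    all_axes = core_axes + shell_axes
    for c, ax in zip(all_centers, all_axes):
        _rasterize_ellipsoid(nuclear, spec.spacing, c, ax)
    shell_channel = farred_mask.data.astype(np.float64)

    off = spec.background_offset
    nuclear = off + (1.0 - off) * nuclear
    shell_channel = off + (1.0 - off) * shell_channel

    if any(s > 0 for s in spec.psf_sigma):
        sigma_vox = [s / sp for s, sp in zip(spec.psf_sigma, spec.spacing)]
        nuclear = ndimage.gaussian_filter(nuclear, sigma=sigma_vox)
        shell_channel = ndimage.gaussian_filter(shell_channel, sigma=sigma_vox)

    if spec.noise_model == "gaussian":
        nuclear = nuclear + rng.normal(0.0, spec.noise_sd, nuclear.shape)
        shell_channel = shell_channel + rng.normal(0.0, spec.noise_sd, nuclear.shape)
    elif spec.noise_model == "poisson":
        nuclear = rng.poisson(np.clip(nuclear, 0, None) * spec.noise_scale) / spec.noise_scale
        shell_channel = (
            rng.poisson(np.clip(shell_channel, 0, None) * spec.noise_scale)
            / spec.noise_scale
        )

    if all_centers:
        centers_arr = np.asarray(all_centers)
        axes_arr = np.asarray(all_axes)
        volumes = 4.0 / 3.0 * math.pi * np.prod(axes_arr, axis=1)
        compartment = np.array(
            [0] * len(core_centers) + [1] * len(shell_centers), dtype=int
        )
    else:
        centers_arr = np.zeros((0, 3))
        axes_arr = np.zeros((0, 3))
        volumes = np.zeros(0)
        compartment = np.zeros(0, dtype=int)

    truth.n_core_nuclei = len(core_centers)
    truth.n_shell_nuclei = len(shell_centers)
    truth.nucleus_centers = centers_arr
    truth.nucleus_semi_axes = axes_arr
    truth.nucleus_volumes = volumes
    truth.nucleus_compartment = compartment

    stack = VoxelStack(
        nuclear=nuclear,
        shell=shell_channel,
        spacing=spec.spacing,
        metadata={"phantom": True, "rng_seed": spec.rng_seed},
    )
    return stack, truth
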