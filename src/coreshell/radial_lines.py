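"""Center-to-surface line analysis in spherical coordinates.

The spheroid is analyzed along digital rays from the nuclear-weighted core
center to quasi-uniformly distributed surface points (a deterministic
spherical Fibonacci lattice stands in for "equally spaced" points).  Each
ray is discretized with a 3D Bresenham line; reading the shell-channel mask
along the line yields, per direction:

* ``shell_thickness`` — number of shell-positive voxels × the
  direction-corrected voxel length (``r`` / line voxel count, which makes
  per-line lengths sum exactly to ``r``);
* ``core_radius`` — number of leading shell-negative voxels before the
  first positive voxel × the same step (undefined when the line has no
  positive voxel);
* ``covered`` — whether any voxel on the line is shell positive.

Angles follow the physics convention used for spheroids sitting in
microwells: azimuth θ ∈ [−π, π] in the x–y plane from +x, and elevation
(polar) φ ∈ [−π/2, π/2] with φ = −π/2 pointing at the well bottom (−z).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stacks import BinaryMask3D

DEFAULT_N_POINTS = 5000
DEFAULT_LAYER_WIDTH = 5.0  # µm
AZIMUTH_BIN = math.pi / 10
POLAR_BIN = math.pi / 20

GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass
class RadialLine:
    """One center-to-surface ray and its shell metrics."""

    theta: float
    phi: float
    surface_point: np.ndarray  # physical µm
    r: float
    path: np.ndarray  # (n, 3) voxel indices, center first
    step: float  # direction-corrected voxel length, µm
    shell_thickness: float
    core_radius: float  # nan when not covered
    covered: bool
    clamped: bool = False  # ray left the grid while still in the mask


def find_core_center(
    dapi_intensity: np.ndarray,
    dapi_mask: BinaryMask3D,
    farred_mask: BinaryMask3D,
) -> np.ndarray:
    """Nuclear-intensity weighted center of mass of the core (µm).

    The core is taken as the nuclear mask minus the shell-channel mask; if
    that difference is empty the unweighted centroid of the whole nuclear
    mask is used instead (with a warning).
    """
    dapi_mask._check_compatible(farred_mask)
    region = dapi_mask.data & ~farred_mask.data
    if not region.any():
        warnings.warn(
            "nuclear mask minus shell mask is empty; "
            "falling back to the unweighted nuclear-mask centroid",
            stacklevel=2,
        )
        region = dapi_mask.data
        weights = np.ones(int(region.sum()))
    else:
        weights = np.asarray(dapi_intensity, float)[region]
        if weights.sum() <= 0:
            weights = np.ones(weights.shape)
    idx = np.argwhere(region).astype(np.float64)
    com_index = np.average(idx, axis=0, weights=weights)
    return com_index * np.asarray(dapi_mask.spacing)


def concentric_layer_ratios(
    whole_mask: BinaryMask3D,
    farred_mask: BinaryMask3D,
    center: np.ndarray,
    layer_width: float = DEFAULT_LAYER_WIDTH,
) -> pd.DataFrame:
    """Shell-channel positive fraction in concentric layers around the center.

    Every in-mask voxel is assigned to layer ``floor(distance / width)``;
    the returned table has one row per non-empty layer with inner/outer
    radii, voxel count and positive fraction.
    """
    if layer_width <= 0:
        raise ValueError("layer_width must be > 0")
    whole_mask._check_compatible(farred_mask)
    sp = np.asarray(whole_mask.spacing)
    idx = np.argwhere(whole_mask.data)
    if idx.size == 0:
        raise ValueError("whole mask is empty")
    dist = np.linalg.norm(idx * sp - np.asarray(center), axis=1)
    layer = np.floor(dist / layer_width).astype(int)
    pos = farred_mask.data[whole_mask.data]
    n_layers = layer.max() + 1
    counts = np.bincount(layer, minlength=n_layers)
    positives = np.bincount(layer, weights=pos.astype(float), minlength=n_layers)
    present = counts > 0
    layers = np.arange(n_layers)[present]
    return pd.DataFrame(
        {
            "layer": layers,
            "inner_um": layers * layer_width,
            "outer_um": (layers + 1) * layer_width,
            "n_voxels": counts[present],
            "farred_fraction": positives[present] / counts[present],
        }
    )


def fibonacci_directions(n: int) -> np.ndarray:
    """Deterministic spherical Fibonacci lattice of ``n`` unit directions.

    Uses the endpoint variant (z from +1 to −1 inclusive) so n = 2 yields
    the two poles; azimuths advance by the golden angle.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n == 1:
        return np.array([[0.0, 0.0, 1.0]])
    i = np.arange(n)
    z = 1.0 - 2.0 * i / (n - 1)
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    az = i * GOLDEN_ANGLE
    return np.column_stack([rho * np.cos(az), rho * np.sin(az), z])


def spherical_angles(vec: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(azimuth θ, elevation φ) of direction vectors; vectorized."""
    vec = np.atleast_2d(vec)
    theta = np.arctan2(vec[:, 1], vec[:, 0])
    norm = np.linalg.norm(vec, axis=1)
    phi = np.arcsin(np.clip(vec[:, 2] / norm, -1.0, 1.0))
    return theta, phi


def direction_from_angles(theta: float, phi: float) -> np.ndarray:
    """Unit vector from azimuth θ and elevation φ."""
    return np.array(
        [math.cos(phi) * math.cos(theta), math.cos(phi) * math.sin(theta), math.sin(phi)]
    )


def sample_surface_points(
    whole_mask: BinaryMask3D,
    center: np.ndarray,
    n_points: int = DEFAULT_N_POINTS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Cast a Fibonacci lattice of rays to the mask surface.

    Returns ``(directions, surface_voxels, r, clamped)`` where
    ``surface_voxels`` holds, per direction, the index of the last in-mask
    voxel along the ray from ``center`` and ``r`` the physical distance to
    it.  ``clamped`` flags rays that left the grid while still inside the
    mask (surface point clamped to the last in-grid voxel).
    """
    center = np.asarray(center, dtype=float)
    sp = np.asarray(whole_mask.spacing)
    shape = np.asarray(whole_mask.shape)
    center_vox = np.floor(center / sp + 0.5).astype(int)
    if not (
        np.all(center_vox >= 0)
        and np.all(center_vox < shape)
        and whole_mask.data[tuple(center_vox)]
    ):
        raise ValueError("center must lie inside the whole mask")
    directions = fibonacci_directions(n_points)

    corners = np.array(
        [[i * (shape[0] - 1), j * (shape[1] - 1), k * (shape[2] - 1)]
         for i in (0, 1) for j in (0, 1) for k in (0, 1)],
        dtype=float,
    ) * sp
    t_max = float(np.max(np.linalg.norm(corners - center, axis=1))) + 1.0
    dt = 0.25 * float(sp.min())
    ts = np.arange(0.0, t_max, dt)

    surface = np.zeros((n_points, 3), dtype=int)
    r = np.zeros(n_points)
    clamped = np.zeros(n_points, dtype=bool)
    chunk = 512
    for lo in range(0, n_points, chunk):
        d = directions[lo : lo + chunk]  # (c, 3)
        pts = center[None, None, :] + ts[None, :, None] * d[:, None, :]
        vox = np.floor(pts / sp + 0.5).astype(int)
        in_grid = np.all((vox >= 0) & (vox < shape), axis=2)
        vox_c = np.clip(vox, 0, shape - 1)
        in_mask = whole_mask.data[vox_c[..., 0], vox_c[..., 1], vox_c[..., 2]]
        in_mask &= in_grid
        # last in-mask sample along each ray
        last = in_mask.shape[1] - 1 - np.argmax(in_mask[:, ::-1], axis=1)
        none_found = ~in_mask.any(axis=1)
        last[none_found] = 0
        sel = vox[np.arange(d.shape[0]), last]
        surface[lo : lo + chunk] = sel
        r[lo : lo + chunk] = np.linalg.norm(sel * sp - center, axis=1)
        # clamped: the last in-mask sample is also the last in-grid sample
        last_in_grid = in_grid.shape[1] - 1 - np.argmax(in_grid[:, ::-1], axis=1)
        clamped[lo : lo + chunk] = in_mask[np.arange(d.shape[0]), last_in_grid]
    if clamped.any():
        warnings.warn(
            f"{int(clamped.sum())} rays left the grid while still inside the mask; "
            "surface points clamped",
            stacklevel=2,
        )
    return directions, surface, r, clamped


def bresenham_3d(start, end) -> np.ndarray:
    """26-connected monotone digital line between two voxel indices.

    Includes both endpoints; the number of voxels is
    ``max per-axis |delta| + 1``.  Implemented as a driving-axis DDA with
    half-up rounding, which yields a Bresenham-family digital line.
    """
    start = np.asarray(start, dtype=np.int64)
    end = np.asarray(end, dtype=np.int64)
    delta = end - start
    n = int(np.abs(delta).max())
    if n == 0:
        return start[None, :].copy()
    ts = np.arange(n + 1, dtype=np.float64) / n
    pts = start[None, :] + ts[:, None] * delta[None, :]
    return np.floor(pts + 0.5).astype(np.int64)


def line_metrics(
    path: np.ndarray, farred_mask: BinaryMask3D, r: float
) -> tuple[float, float, bool, float]:
    """Shell thickness, core radius and coverage flag for one line.

    ``step = r / len(path)`` (the direction-corrected voxel length);
    thickness counts all shell-positive voxels on the line; the core radius
    is the leading-negative run length and is NaN for uncovered lines
    (excluded from core-radius statistics).  Returns
    ``(thickness, core_radius, covered, step)``.
    """
    if path.shape[0] == 0:
        raise ValueError("empty line")
    values = farred_mask.data[path[:, 0], path[:, 1], path[:, 2]]
    n = path.shape[0]
    step = r / n if n else 0.0
    n_pos = int(values.sum())
    if n_pos == 0:
        return 0.0, float("nan"), False, step
    first_pos = int(np.argmax(values))
    return n_pos * step, first_pos * step, True, step


def trace_lines(
    whole_mask: BinaryMask3D,
    farred_mask: BinaryMask3D,
    center: np.ndarray,
    n_points: int = DEFAULT_N_POINTS,
) -> list[RadialLine]:
    """Full line analysis: sample surface, run Bresenham, read the shell mask."""
    whole_mask._check_compatible(farred_mask)
    sp = np.asarray(whole_mask.spacing)
    center = np.asarray(center, dtype=float)
    center_vox = np.floor(center / sp + 0.5).astype(int)
    _, surface, r_all, clamped = sample_surface_points(whole_mask, center, n_points)
    lines: list[RadialLine] = []
    for k in range(n_points):
        path = bresenham_3d(center_vox, surface[k])
        offset = surface[k] * sp - center
        r = float(r_all[k])
        if r == 0.0:
            theta, phi = 0.0, 0.0
        else:
            theta = math.atan2(offset[1], offset[0])
            phi = math.asin(min(1.0, max(-1.0, offset[2] / r)))
        thickness, core_r, covered, step = line_metrics(path, farred_mask, r)
        lines.append(
            RadialLine(
                theta=theta,
                phi=phi,
                surface_point=surface[k] * sp,
                r=r,
                path=path,
                step=step,
                shell_thickness=thickness,
                core_radius=core_r,
                covered=covered,
                clamped=bool(clamped[k]),
            )
        )
    return lines


def lines_table(lines: list[RadialLine]) -> pd.DataFrame:
    """Per-line table (θ, φ, r, thickness, core radius, covered)."""
    return pd.DataFrame(
        {
            "theta": [ln.theta for ln in lines],
            "phi": [ln.phi for ln in lines],
            "r_um": [ln.r for ln in lines],
            "shell_thickness_um": [ln.shell_thickness for ln in lines],
            "core_radius_um": [ln.core_radius for ln in lines],
            "covered": [ln.covered for ln in lines],
        }
    )


def aggregate_lines(lines: list[RadialLine]) -> dict:
    """Per-spheroid summary of the line analysis.

    The thickness mean is reported both over all lines (uncovered lines
    contribute 0) and over covered lines only; the core radius is averaged
    over covered lines only, since it is undefined elsewhere.
    """
    if not lines:
        raise ValueError("no lines to aggregate")
    t = lines_table(lines)
    covered = t["covered"].to_numpy(bool)
    n = len(t)
    summary = {
        "n_lines": n,
        "coverage_percent": 100.0 * covered.sum() / n,
        "mean_radius_um": float(t["r_um"].mean()),
        "sd_radius_um": float(t["r_um"].std(ddof=1)) if n > 1 else float("nan"),
        "mean_shell_thickness_um": float(t["shell_thickness_um"].mean()),
        "sd_shell_thickness_um": (
            float(t["shell_thickness_um"].std(ddof=1)) if n > 1 else float("nan")
        ),
        "mean_shell_thickness_covered_um": (
            float(t.loc[covered, "shell_thickness_um"].mean()) if covered.any() else 0.0
        ),
        "mean_core_radius_um": (
            float(t.loc[covered, "core_radius_um"].mean())
            if covered.any()
            else float("nan")
        ),
        "sd_core_radius_um": (
            float(t.loc[covered, "core_radius_um"].std(ddof=1))
            if covered.sum() > 1
            else float("nan")
        ),
    }
    return summary


def angular_trend(
    lines: list[RadialLine],
    axis: str = "polar",
    bin_width: float | None = None,
) -> pd.DataFrame:
    """Mean ± sd shell thickness in fixed-width angular bins.

    Azimuth bins span [−π, π] (default width π/10, 20 bins); polar bins
    span [−π/2, π/2] (default width π/20, 20 bins).  Empty bins are
    reported with NaN mean (no-data marker) and n = 0.
    """
    if axis == "azimuth":
        lo, hi = -math.pi, math.pi
        width = AZIMUTH_BIN if bin_width is None else bin_width
        values = np.array([ln.theta for ln in lines])
    elif axis == "polar":
        lo, hi = -math.pi / 2, math.pi / 2
        width = POLAR_BIN if bin_width is None else bin_width
        values = np.array([ln.phi for ln in lines])
    else:
        raise ValueError("axis must be 'azimuth' or 'polar'")
    n_bins = (hi - lo) / width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin_width {width} does not divide the angular range")
    n_bins = int(round(n_bins))
    thickness = np.array([ln.shell_thickness for ln in lines])
    which = np.clip(np.floor((values - lo) / width).astype(int), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = thickness[which == b]
        rows.append(
            {
                "bin_left": lo + b * width,
                "bin_right": lo + (b + 1) * width,
                "bin_center": lo + (b + 0.5) * width,
                "mean_thickness_um": float(sel.mean()) if sel.size else float("nan"),
                "sd_thickness_um": float(sel.std(ddof=1)) if sel.size > 1 else float("nan"),
                "n": int(sel.size),
            }
        )
    return pd.DataFrame(rows)
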