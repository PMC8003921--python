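"""Two-pass seeded watershed separation of the nuclear-channel mask.

Seeds are the regional minima of the negated Euclidean distance transform
after H-minima suppression at depth ``h`` (µm); the watershed floods the
negated distance transform from those seeds within the mask.  A single
refinement pass removes seeds whose basin came out smaller than a fraction
(default 70%) of the median basin volume and re-floods, which limits
over-segmentation of touching nuclei.

The distance transform always uses the physical spacing, so the module is
anisotropy-aware even when upstream isotropic interpolation is skipped.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import h_minima
from skimage.segmentation import watershed

from .stacks import BinaryMask3D, LabelVolume

DEFAULT_H = 1.0  # µm
DEFAULT_REFINE_FRACTION = 0.70


class NoSeedsError(RuntimeError):
    """Raised when the watershed has no seeds; lower ``h`` and retry."""


def _neg_distance(mask: BinaryMask3D) -> np.ndarray:
    dist = ndimage.distance_transform_edt(mask.data, sampling=mask.spacing)
    return -dist


def make_seeds(mask: BinaryMask3D, h: float = DEFAULT_H) -> np.ndarray:
    """Seed label grid from H-minima of the negated distance transform.

    Regional minima of depth < ``h`` (µm) are suppressed; the surviving
    minima plateaus are labelled as 26-connected components.  Every seed
    voxel lies inside the mask; an empty mask yields zero seeds.
    """
    if h < 0:
        raise ValueError("h must be >= 0")
    seeds = np.zeros(mask.shape, dtype=np.int32)
    if not mask.data.any():
        return seeds
    neg = _neg_distance(mask)
    if h == 0:
        from skimage.morphology import local_minima

        minima = local_minima(neg, connectivity=3)
    else:
        minima = h_minima(neg, h).astype(bool)
    minima &= mask.data
    structure = ndimage.generate_binary_structure(3, 3)
    ndimage.label(minima, structure=structure, output=seeds)
    return seeds


def seeded_watershed(mask: BinaryMask3D, seeds: np.ndarray) -> LabelVolume:
    """Flood the negated distance transform from ``seeds`` within the mask.

    Every mask voxel is assigned to exactly one seed's catchment basin;
    background stays 0.  Flooding ties are broken by the deterministic
    raster scan order of the priority flood, so results are reproducible.
    """
    if seeds.max(initial=0) < 1:
        raise NoSeedsError("no seeds supplied; lower the H-minima depth h")
    neg = _neg_distance(mask)
    labels = watershed(neg, markers=seeds, mask=mask.data, connectivity=3)
    return LabelVolume(labels.astype(np.int32), mask.spacing)


def refine_watershed(
    labels: LabelVolume,
    mask: BinaryMask3D,
    seeds: np.ndarray,
    fraction: float = DEFAULT_REFINE_FRACTION,
) -> LabelVolume:
    """Second watershed pass after dropping seeds of undersized basins.

    Basins with volume below ``fraction · median(basin volumes)`` lose their
    seeds and the watershed is re-run, redistributing their territory to the
    surviving basins.  If nothing is below threshold the input is returned
    unchanged.  If all seeds would be removed, the seed of the largest basin
    is kept (with a warning).
    """
    if not 0 <= fraction:
        raise ValueError("fraction must be >= 0")
    ids = labels.label_ids()
    if ids.size <= 1:
        return labels
    volumes = labels.label_volumes()
    threshold = fraction * float(np.median(volumes))
    small = ids[volumes < threshold]
    if small.size == 0:
        return labels
    if small.size == ids.size:
        keep_id = ids[int(np.argmax(volumes))]
        small = ids[ids != keep_id]
        warnings.warn(
            "all basins below the refinement threshold; keeping the largest seed",
            stacklevel=2,
        )
    surviving = seeds.copy()
    surviving[np.isin(surviving, small)] = 0
    return seeded_watershed(mask, surviving)


def separate_nuclei(
    mask: BinaryMask3D,
    h: float = DEFAULT_H,
    refine_fraction: float = DEFAULT_REFINE_FRACTION,
) -> LabelVolume:
    """Full two-pass pipeline: seeds → watershed → one refinement pass."""
    seeds = make_seeds(mask, h=h)
    labels = seeded_watershed(mask, seeds)
    return refine_watershed(labels, mask, seeds, fraction=refine_fraction)


def median_nucleus_volume(labels: LabelVolume) -> float:
    """Median physical volume (µm³) of the separated nuclei."""
    volumes = labels.label_volumes()
    if volumes.size == 0:
        raise ValueError("empty labeling has no median nucleus volume")
    return float(np.median(volumes))


def nucleus_table(labels: LabelVolume) -> pd.DataFrame:
    """Per-nucleus table: label id, volume (µm³), centroid (µm, x/y/z)."""
    ids = labels.label_ids()
    volumes = labels.label_volumes()
    centroids = ndimage.center_of_mass(
        np.ones(labels.labels.shape), labels.labels, ids
    )
    centroids = np.asarray(centroids).reshape(-1, 3) * np.asarray(labels.spacing)
    return pd.DataFrame(
        {
            "label": ids,
            "volume_um3": volumes,
            "x_um": centroids[:, 0],
            "y_um": centroids[:, 1],
            "z_um": centroids[:, 2],
        }
    )
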