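"""Core in-memory containers for two-channel spheroid stacks.

Conventions used throughout the package:

* voxel grids are numpy arrays indexed ``[ix, iy, iz]`` (x, y, z order);
* ``spacing`` is the physical voxel pitch ``(sx, sy, sz)`` in micrometres;
* the physical position of voxel ``(i, j, k)`` is ``(i*sx, j*sy, k*sz)``,
  i.e. coordinates refer to voxel centers with the first center at the
  origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Spacing = tuple[float, float, float]


def _check_spacing(spacing: Spacing) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive values, got {spacing!r}")
    return spacing


@dataclass
class VoxelStack:
    """A two-channel 3D intensity stack with physical voxel spacing.

    Channels are the nuclear stain (all nuclei, e.g. DAPI) and the
    shell-cell stain (pre-seeding cytoplasmic dye, e.g. Far Red DDAO-SE).
    """

    nuclear: np.ndarray
    shell: np.ndarray
    spacing: Spacing
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nuclear = np.asarray(self.nuclear)
        self.shell = np.asarray(self.shell)
        if self.nuclear.ndim != 3 or self.shell.ndim != 3:
            raise ValueError("channels must be 3D arrays")
        if self.nuclear.shape != self.shell.shape:
            raise ValueError(
                f"channel shapes differ: {self.nuclear.shape} vs {self.shell.shape}"
            )
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.nuclear.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in µm³."""
        return float(np.prod(self.spacing))


@dataclass
class BinaryMask3D:
    """A boolean voxel grid with physical spacing."""

    data: np.ndarray
    spacing: Spacing

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume(self) -> float:
        """Total physical volume of the mask in µm³."""
        return float(np.count_nonzero(self.data)) * self.voxel_volume

    def __and__(self, other: "BinaryMask3D") -> "BinaryMask3D":
        self._check_compatible(other)
        return BinaryMask3D(self.data & other.data, self.spacing)

    def __or__(self, other: "BinaryMask3D") -> "BinaryMask3D":
        self._check_compatible(other)
        return BinaryMask3D(self.data | other.data, self.spacing)

    def __invert__(self) -> "BinaryMask3D":
        return BinaryMask3D(~self.data, self.spacing)

    def difference(self, other: "BinaryMask3D") -> "BinaryMask3D":
        self._check_compatible(other)
        return BinaryMask3D(self.data & ~other.data, self.spacing)

    def _check_compatible(self, other: "BinaryMask3D") -> None:
        if self.shape != other.shape:
            raise ValueError(f"mask shapes differ: {self.shape} vs {other.shape}")
        if not np.allclose(self.spacing, other.spacing):
            raise ValueError(f"mask spacings differ: {self.spacing} vs {other.spacing}")


@dataclass
class LabelVolume:
    """Integer-labelled voxel grid (0 = background) with physical spacing."""

    labels: np.ndarray
    spacing: Spacing

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label grid must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer typed")
        self.spacing = _check_spacing(self.spacing)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_labels(self) -> int:
        return int(self.labels.max(initial=0))

    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def label_volumes(self) -> np.ndarray:
        """Physical volume (µm³) of each label, ordered by label id."""
        ids = self.label_ids()
        counts = np.bincount(self.labels.ravel())[ids]
        return counts * self.voxel_volume

    def as_mask(self) -> BinaryMask3D:
        return BinaryMask3D(self.labels > 0, self.spacing)
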