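"""TIFF/OME-TIFF reading and writing for two-channel spheroid stacks.

In-memory arrays use (x, y, z) index order; on disk the OME convention
(C, Z, Y, X) is used, with physical voxel sizes recorded as
``PhysicalSizeX/Y/Z`` metadata.
"""

from __future__ import annotations

import json
from pathlib import Path
from xml.etree import ElementTree

import numpy as np
import tifffile

from .phantom import GroundTruth
from .stacks import BinaryMask3D, LabelVolume, VoxelStack


class StackReadError(ValueError):
    """Raised when a file cannot be interpreted as a two-channel stack."""


def _to_disk_order(arr: np.ndarray) -> np.ndarray:
    # (x, y, z) -> (z, y, x)
    return np.ascontiguousarray(arr.transpose(2, 1, 0))


def _from_disk_order(arr: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(arr.transpose(2, 1, 0))


def write_stack(path: str | Path, stack: VoxelStack) -> None:
    """Write a two-channel stack as OME-TIFF with physical-size metadata."""
    data = np.stack(
        [_to_disk_order(np.asarray(stack.nuclear, np.float32)),
         _to_disk_order(np.asarray(stack.shell, np.float32))]
    )  # (C, Z, Y, X)
    sx, sy, sz = stack.spacing
    tifffile.imwrite(
        str(path),
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "PhysicalSizeX": sx,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": sy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": sz,
            "PhysicalSizeZUnit": "µm",
            "Channel": {"Name": ["DAPI", "FarRed"]},
        },
    )


def _ome_spacing(tif: tifffile.TiffFile) -> tuple[float, float, float] | None:
    if not tif.ome_metadata:
        return None
    try:
        root = ElementTree.fromstring(tif.ome_metadata)
    except ElementTree.ParseError:
        return None
    for pixels in root.iter():
        if pixels.tag.endswith("Pixels"):
            try:
                return (
                    float(pixels.attrib["PhysicalSizeX"]),
                    float(pixels.attrib["PhysicalSizeY"]),
                    float(pixels.attrib["PhysicalSizeZ"]),
                )
            except KeyError:
                return None
    return None


def read_stack(
    path: str | Path,
    channels: tuple[int, int] = (0, 1),
    spacing: tuple[float, float, float] | None = None,
) -> VoxelStack:
    """Read a ≥2-channel TIFF/OME-TIFF into a :class:`VoxelStack`.

    ``channels`` maps (nuclear, shell) to channel indices.  Physical
    spacing comes from OME metadata; pass ``spacing`` to override or when
    the file has none (plain TIFF), otherwise the call fails loudly.
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tif:
        series = tif.series[0]
        arr = series.asarray()
        axes = series.axes  # e.g. 'CZYX'
        meta_spacing = _ome_spacing(tif)

    axes = axes.replace("S", "C")
    if sorted(axes) != ["C", "X", "Y", "Z"]:
        # plain TIFFs carry unnamed axes; assume (C, Z, Y, X) with the
        # channel axis the leading (smaller) one
        if arr.ndim == 4:
            axes = "CZYX" if arr.shape[0] <= arr.shape[1] else "ZCYX"
        else:
            raise StackReadError(
                f"{path.name}: no channel axis found (axes={axes!r}, "
                f"shape={arr.shape}); a two-channel stack is required"
            )
    order = [axes.index(a) for a in "CZYX"]
    arr = np.transpose(arr, order)  # (C, Z, Y, X)
    n_channels = arr.shape[0]
    if max(channels) >= n_channels:
        raise StackReadError(
            f"{path.name}: requested channels {channels} but file has {n_channels}"
        )
    if spacing is None:
        spacing = meta_spacing
    if spacing is None:
        raise StackReadError(
            f"{path.name}: no physical voxel size in metadata; "
            "pass spacing explicitly (e.g. --spacing-x/y/z on the CLI)"
        )
    return VoxelStack(
        nuclear=_from_disk_order(arr[channels[0]]).astype(np.float64),
        shell=_from_disk_order(arr[channels[1]]).astype(np.float64),
        spacing=tuple(float(s) for s in spacing),
        metadata={"source": str(path)},
    )


def write_mask(path: str | Path, mask: BinaryMask3D) -> None:
    """Write a binary mask as an 8-bit (0/255) single-channel OME-TIFF."""
    data = _to_disk_order((mask.data.astype(np.uint8)) * 255)
    sx, sy, sz = mask.spacing
    tifffile.imwrite(
        str(path),
        data,
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeX": sx,
            "PhysicalSizeY": sy,
            "PhysicalSizeZ": sz,
        },
    )


def write_labels(path: str | Path, labels: LabelVolume) -> None:
    """Write a label volume as 16-bit OME-TIFF."""
    data = _to_disk_order(labels.labels.astype(np.uint16))
    sx, sy, sz = labels.spacing
    tifffile.imwrite(
        str(path),
        data,
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeX": sx,
            "PhysicalSizeY": sy,
            "PhysicalSizeZ": sz,
        },
    )


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2))
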