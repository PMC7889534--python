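"""Reading and writing the standard formats used by the pipeline.

Stacks travel as multi-page TIFF / OME-TIFF with a channel axis (CZYX);
masks as 16-bit labelled TIFF; tabular results as CSV with units recorded
in the column names; parameters and manifests as JSON sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import tifffile

from .geometry import CHANNELS, MultiChannelStack, StackGeometry
from .segment import NucleusMask


def write_stack(path, stack: MultiChannelStack,
                channel_order: Sequence[str] = CHANNELS) -> None:
    """Write a multi-channel stack as OME-TIFF (axes CZYX, float32), with
    the voxel pitch recorded in the OME metadata."""
    geom = stack.geometry
    data = np.stack([stack[c] for c in channel_order]).astype(np.float32)
    tifffile.imwrite(
        str(path), data, ome=True,
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": list(channel_order)},
            "PhysicalSizeX": geom.dx, "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": geom.dy, "PhysicalSizeYUnit": "µm",
            "PhysicalSizeZ": geom.dz, "PhysicalSizeZUnit": "µm",
        },
    )


def read_stack(path, voxel_um: Optional[Sequence[float]] = None,
               channel_order: Sequence[str] = CHANNELS
               ) -> MultiChannelStack:
    """Read a CZYX TIFF written by :func:`write_stack` (or compatible).

    ``voxel_um`` overrides the pitch; otherwise it is taken from the OME
    metadata when present.
    """
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        meta_pitch = None
        if tf.ome_metadata:
            import re

            m = {ax: re.search(
                    rf'PhysicalSize{ax}="([0-9.eE+-]+)"', tf.ome_metadata)
                 for ax in "XYZ"}
            if all(m.values()):
                meta_pitch = tuple(float(m[ax].group(1)) for ax in "XYZ")
    if data.ndim != 4:
        raise ValueError(f"expected a CZYX stack, got shape {data.shape}")
    if data.shape[0] != len(channel_order):
        raise ValueError(
            f"stack has {data.shape[0]} channels, expected "
            f"{len(channel_order)}")
    pitch = tuple(voxel_um) if voxel_um is not None else meta_pitch
    if pitch is None:
        raise ValueError("voxel size not in metadata; pass voxel_um")
    nz, ny, nx = data.shape[1:]
    geom = StackGeometry(nx, ny, nz, *pitch)
    channels = {name: data[i].astype(np.float64)
                for i, name in enumerate(channel_order)}
    return MultiChannelStack(geometry=geom, channels=channels)


def write_label_masks(path, masks: Sequence[NucleusMask],
                      geometry: StackGeometry) -> None:
    """All nucleus masks of one FOV as a 16-bit label stack
    (label = nucleus id + 1; 0 = background)."""
    labels = np.zeros(geometry.shape, dtype=np.uint16)
    for m in masks:
        z0, z1, y0, y1, x0, x1 = m.bbox
        region = labels[z0:z1, y0:y1, x0:x1]
        region[m.mask] = m.id + 1
    tifffile.imwrite(str(path), labels)


def write_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, Path):
            return str(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_default) + "\n")
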