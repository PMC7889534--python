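"""Voxel geometry and the multi-channel stack container.

Coordinate conventions used throughout the package:

* Arrays are indexed ``[z, y, x]`` (the scikit-image convention).
* Physical positions are 3-vectors ``(x, y, z)`` in micrometres.
* The physical position of a voxel centre is ``(index + 0.5) * pitch``
  per axis; voxel indices are 0-based and bounding boxes half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

#: Default voxel pitch in μm (widefield stack, 60x/NA 1.4): 108 nm lateral,
#: 293 nm axial.
DEFAULT_VOXEL_UM = (0.108, 0.108, 0.293)

CHANNELS = ("DAPI", "FITC", "TRITC")


@dataclass(frozen=True)
class StackGeometry:
    """Field size in voxels plus physical voxel pitch in μm."""

    nx: int
    ny: int
    nz: int
    dx: float = DEFAULT_VOXEL_UM[0]
    dy: float = DEFAULT_VOXEL_UM[1]
    dz: float = DEFAULT_VOXEL_UM[2]

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) <= 0:
            raise ValueError("field size must be positive in every axis")
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("voxel pitch must be positive in every axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Array shape ``(nz, ny, nx)``."""
        return (self.nz, self.ny, self.nx)

    @property
    def voxel_um(self) -> np.ndarray:
        """Voxel pitch as an ``(dx, dy, dz)`` vector in μm."""
        return np.array([self.dx, self.dy, self.dz])

    @property
    def voxel_volume_um3(self) -> float:
        return self.dx * self.dy * self.dz

    @property
    def extent_um(self) -> np.ndarray:
        """Physical field extent ``(x, y, z)`` in μm."""
        return np.array([self.nx, self.ny, self.nz]) * self.voxel_um

    def voxel_center_um(self, index_xyz) -> np.ndarray:
        """Physical centre (μm) of the voxel at integer index ``(ix, iy, iz)``."""
        return (np.asarray(index_xyz, dtype=float) + 0.5) * self.voxel_um

    def um_to_voxel(self, pos_um) -> np.ndarray:
        """Continuous voxel coordinate of a physical position (inverse of
        :meth:`voxel_center_um`; a voxel centre maps to its integer index)."""
        return np.asarray(pos_um, dtype=float) / self.voxel_um - 0.5


@dataclass
class MultiChannelStack:
    """Named 3D intensity arrays sharing one :class:`StackGeometry`.

    Channels are stored as ``(nz, ny, nx)`` float arrays keyed by name
    (conventionally DAPI, FITC, TRITC).
    """

    geometry: StackGeometry
    channels: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.channels.items():
            if arr.shape != self.geometry.shape:
                raise ValueError(
                    f"channel {name!r} has shape {arr.shape}, "
                    f"expected {self.geometry.shape}"
                )

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels
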