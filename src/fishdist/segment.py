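"""Preprocessing and 3D nucleus segmentation from the DAPI channel.

The segmentation follows a seed-then-refine scheme: the DAPI stack is
max-projected to 2D, smoothed with a wide Gaussian (sigma_xy = 3.75 μm,
about the radius of a fibroblast nucleus), and local maxima of the
smoothed projection seed square boxes (45 x 45 μm^2 by default, full stack
height).  Boxes that capture more than one maximum are discarded rather
than declumped.  Within each box the nucleus is segmented slice by slice:
each z-slice is filtered at several Gaussian scales, thresholded per scale
(Otsu), and the binary votes are combined by majority.  The assembled 3D
mask is then refined by a global rule — voxels dimmer than 0.6 x the
global (Otsu) threshold of the box are background — which removes the
blurred out-of-focus caps above and below the nucleus.  Finally the
connected component under the seed is kept and nuclei with extreme volume
or touching the lateral field border are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .geometry import MultiChannelStack, StackGeometry


@dataclass
class SegmentationParams:
    seed_sigma_um: float = 3.75  # MIP smoothing scale for seed finding
    box_side_um: float = 45.0  # side of the per-nucleus bounding square
    prominence_frac: float = 0.05  # maxima floor, fraction of dynamic range
    slice_sigmas_um: Sequence[float] = (0.5, 1.0, 2.0)
    min_votes: int = 2  # strict majority of the 3 scales
    global_factor: float = 0.6  # refinement: below factor x Otsu = background
    volume_bounds_um3: Tuple[float, float] = (200.0, 4000.0)

    def validate(self) -> None:
        if not 0.0 < self.global_factor < 1.0:
            raise ValueError("global_factor must lie in (0, 1)")
        if self.box_side_um <= 2.0 * self.seed_sigma_um:
            raise ValueError("box side must exceed twice the seed sigma")
        if not 1 <= self.min_votes <= len(self.slice_sigmas_um):
            raise ValueError("min_votes out of range")


@dataclass
class SeedBox:
    """A candidate nucleus bounding box: full stack height, square in XY."""

    center_xy_vox: Tuple[int, int]  # (ix, iy) on the filtered MIP
    x0: int
    x1: int
    y0: int
    y1: int


@dataclass
class NucleusMask:
    """One segmented nucleus: half-open voxel bounding box + binary mask."""

    id: int
    bbox: Tuple[int, int, int, int, int, int]  # (z0, z1, y0, y1, x0, x1)
    mask: np.ndarray  # bool, shape matching the bbox
    volume_um3: float
    touches_border: bool = False
    volume_outlier: bool = False
    reason: Optional[str] = None

    @property
    def accepted(self) -> bool:
        return not (self.touches_border or self.volume_outlier) and \
            self.reason is None

    def full_mask(self, geometry: StackGeometry) -> np.ndarray:
        out = np.zeros(geometry.shape, dtype=bool)
        z0, z1, y0, y1, x0, x1 = self.bbox
        out[z0:z1, y0:y1, x0:x1] = self.mask
        return out

    def centroid_um(self, geometry: StackGeometry) -> np.ndarray:
        z0, z1, y0, y1, x0, x1 = self.bbox
        zz, yy, xx = np.nonzero(self.mask)
        c_vox = np.array([xx.mean() + x0, yy.mean() + y0, zz.mean() + z0])
        return (c_vox + 0.5) * geometry.voxel_um


def normalize_stack(stack: MultiChannelStack) -> MultiChannelStack:
    """Min/max-normalise every channel to [0, 1].

    A constant channel maps to all zeros.  Idempotent; raises on non-finite
    voxels.
    """
    out = {}
    for name, arr in stack.channels.items():
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"channel {name!r} contains non-finite voxels")
        lo = float(arr.min())
        hi = float(arr.max())
        if hi > lo:
            out[name] = (arr - lo) / (hi - lo)
        else:
            out[name] = np.zeros_like(arr, dtype=np.float64)
    return MultiChannelStack(geometry=stack.geometry, channels=out)


def find_nucleus_seeds(dapi: np.ndarray, geometry: StackGeometry,
                       params: SegmentationParams) -> List[SeedBox]:
    """Seed candidate nucleus boxes from the smoothed DAPI MIP.

    Local maxima of the sigma-filtered maximum intensity projection mark
    box centres; only boxes containing exactly one maximum are returned.
    """
    params.validate()
    mip = dapi.max(axis=0)
    sig = (params.seed_sigma_um / geometry.dy,
           params.seed_sigma_um / geometry.dx)
    filtered = ndimage.gaussian_filter(mip, sigma=sig)
    rng_span = float(filtered.max() - filtered.min())
    if rng_span <= 0:
        return []
    floor = float(filtered.min()) + params.prominence_frac * rng_span
    # local maxima above the floor; connected equal-valued plateaus are
    # merged into a single maximum at their centroid
    is_max = (filtered == ndimage.maximum_filter(filtered, size=3)) \
        & (filtered >= floor)
    labels, n_lab = ndimage.label(is_max)
    if n_lab == 0:
        return []
    centroids = ndimage.center_of_mass(is_max, labels,
                                       np.arange(1, n_lab + 1))
    maxima = np.rint(np.asarray(centroids)).astype(int)  # rows of (iy, ix)
    half_x = int(round(params.box_side_um / (2.0 * geometry.dx)))
    half_y = int(round(params.box_side_um / (2.0 * geometry.dy)))
    boxes: List[SeedBox] = []
    for iy, ix in maxima:
        x0, x1 = ix - half_x, ix + half_x
        y0, y1 = iy - half_y, iy + half_y
        inside = np.sum(
            (maxima[:, 1] >= x0) & (maxima[:, 1] < x1)
            & (maxima[:, 0] >= y0) & (maxima[:, 0] < y1)
        )
        if inside == 1:
            boxes.append(SeedBox(
                center_xy_vox=(int(ix), int(iy)),
                x0=max(x0, 0), x1=min(x1, geometry.nx),
                y0=max(y0, 0), y1=min(y1, geometry.ny),
            ))
    return boxes


def _slice_votes(sl: np.ndarray, sigmas_vox: Sequence[Tuple[float, float]],
                 min_votes: int) -> np.ndarray:
    votes = np.zeros(sl.shape, dtype=np.int8)
    for sig in sigmas_vox:
        sm = ndimage.gaussian_filter(sl, sigma=sig)
        span = float(sm.max() - sm.min())
        if span <= 1e-9:
            continue  # flat slice: no foreground vote at this scale
        t = threshold_otsu(sm)
        votes += sm > t
    return votes >= min_votes


def segment_nucleus_3d(dapi: np.ndarray, box: SeedBox,
                       geometry: StackGeometry,
                       params: SegmentationParams,
                       nucleus_id: int = 0) -> NucleusMask:
    """Segment the nucleus inside one seed box.

    Returns a :class:`NucleusMask`; a mask that is empty after refinement
    carries ``reason='empty'`` and is never accepted.
    """
    params.validate()
    sub = dapi[:, box.y0:box.y1, box.x0:box.x1]
    sigmas_vox = [(s / geometry.dy, s / geometry.dx)
                  for s in params.slice_sigmas_um]

    mask3d = np.zeros(sub.shape, dtype=bool)
    for iz in range(sub.shape[0]):
        mask3d[iz] = _slice_votes(sub[iz], sigmas_vox, params.min_votes)

    # global refinement: 0.6 x global Otsu threshold of the box
    span = float(sub.max() - sub.min())
    if span <= 1e-9:
        return NucleusMask(nucleus_id, (0, sub.shape[0], box.y0, box.y1,
                                        box.x0, box.x1),
                           np.zeros(sub.shape, bool), 0.0, reason="empty")
    t_global = threshold_otsu(sub)
    mask3d &= sub >= params.global_factor * t_global

    labels, n_lab = ndimage.label(mask3d)
    if n_lab == 0:
        return NucleusMask(nucleus_id, (0, sub.shape[0], box.y0, box.y1,
                                        box.x0, box.x1),
                           mask3d, 0.0, reason="empty")
    # component under the seed: the label column at the box centre; fall
    # back to the largest component if the centre column is empty
    cx = min(box.center_xy_vox[0] - box.x0, sub.shape[2] - 1)
    cy = min(box.center_xy_vox[1] - box.y0, sub.shape[1] - 1)
    col = labels[:, cy, cx]
    col = col[col > 0]
    if col.size:
        keep = int(np.bincount(col).argmax())
    else:
        keep = int(np.argmax(ndimage.sum_labels(
            np.ones_like(labels), labels, np.arange(1, n_lab + 1)))) + 1
    mask3d = labels == keep

    volume = float(mask3d.sum()) * geometry.voxel_volume_um3
    return NucleusMask(
        id=nucleus_id,
        bbox=(0, sub.shape[0], box.y0, box.y1, box.x0, box.x1),
        mask=mask3d,
        volume_um3=volume,
    )


def filter_nuclei(masks: Sequence[NucleusMask], params: SegmentationParams,
                  geometry: StackGeometry
                  ) -> Tuple[List[NucleusMask], List[NucleusMask]]:
    """Apply the volume and XY-border rejection rules.

    Returns ``(accepted, rejected)``; every rejected mask carries a reason
    code.  The border test applies to the lateral (XY) field borders only —
    stacks deliberately over-range in z.
    """
    vmin, vmax = params.volume_bounds_um3
    accepted, rejected = [], []
    for m in masks:
        if m.reason is not None:
            rejected.append(m)
            continue
        z0, z1, y0, y1, x0, x1 = m.bbox
        any_z, any_y, any_x = (m.mask.any(axis=(1, 2)),
                               m.mask.any(axis=(0, 2)),
                               m.mask.any(axis=(0, 1)))
        touches = (
            (x0 == 0 and any_x[0]) or (x1 == geometry.nx and any_x[-1])
            or (y0 == 0 and any_y[0]) or (y1 == geometry.ny and any_y[-1])
        )
        m.touches_border = bool(touches)
        m.volume_outlier = not (vmin <= m.volume_um3 <= vmax)
        if m.touches_border:
            m.reason = "border"
            rejected.append(m)
        elif m.volume_outlier:
            m.reason = "volume"
            rejected.append(m)
        else:
            accepted.append(m)
    return accepted, rejected


def segment_field(dapi: np.ndarray, geometry: StackGeometry,
                  params: Optional[SegmentationParams] = None
                  ) -> Tuple[List[NucleusMask], List[NucleusMask]]:
    """Convenience: seeds -> per-box segmentation -> filtering for one FOV."""
    params = params or SegmentationParams()
    boxes = find_nucleus_seeds(dapi, geometry, params)
    masks = [segment_nucleus_3d(dapi, b, geometry, params, nucleus_id=i)
             for i, b in enumerate(boxes)]
    return filter_nuclei(masks, params, geometry)
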