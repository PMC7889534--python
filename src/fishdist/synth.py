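"""Seeded simulator of multi-channel 3D FISH stacks with full ground truth.

The simulator emulates the imaging scenario the analysis pipeline is built
for: fibroblast-like nuclei sparse on a widefield field of view, imaged in
three channels — DAPI outlining the nuclear volume, and FITC/TRITC carrying
two diffraction-limited FISH spots per channel per nucleus (the two alleles
of a gene locus and of the matching subtelomeric probe).  Each FITC/TRITC
spot pair is either *interacting* (3D separation well below 500 nm, so the
two spots fall within the same point spread function) or *non-interacting*
(separation 0.5–3 μm).  The TRITC channel is rendered with a constant
chromatic offset, probe clutter is scattered outside the nuclei, and
Poisson shot noise plus Gaussian read noise are applied.

Every random draw goes through one :class:`numpy.random.Generator` seeded
from :attr:`SimParams.seed`, so identical parameters give bit-identical
stacks and ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.special import erf

from .geometry import DEFAULT_VOXEL_UM, MultiChannelStack, StackGeometry

_SQRT2 = np.sqrt(2.0)


class PackingError(RuntimeError):
    """Raised when the requested nuclei cannot be placed with the required
    bounding-box separation."""


@dataclass
class SimParams:
    """Parameters of one simulated field of view.

    Defaults reproduce the nominal acquisition geometry (108x108x293 nm
    voxels) and the two-allele FISH scenario: 2 spots per channel per
    nucleus, an interacting fraction ``p_int`` of pairs drawn from a
    half-normal law with 120 nm scale (so essentially all interacting
    distances are below 500 nm) and the remainder uniform on 0.5-3 μm.
    """

    field_shape: Tuple[int, int, int] = (900, 900, 61)  # (nx, ny, nz)
    voxel_um: Tuple[float, float, float] = DEFAULT_VOXEL_UM
    n_nuclei: int = 4
    nucleus_semiaxes_um: Tuple[float, float, float] = (7.0, 5.0, 2.5)
    semiaxis_jitter: float = 0.08  # fractional s.d. of per-nucleus jitter
    spots_per_channel: int = 2
    p_int: float = 0.9
    interacting_scale_um: float = 0.12  # half-normal scale
    noninteracting_range_um: Tuple[float, float] = (0.5, 3.0)
    chromatic_offset_um: Tuple[float, float, float] = (0.12, -0.08, 0.15)
    psf_sigma_um: Tuple[float, float, float] = (0.15, 0.15, 0.4)
    spot_photons: float = 3000.0  # integrated photons per FISH spot
    background_photons: float = 50.0  # per-voxel baseline in FITC/TRITC
    dapi_photons: float = 400.0  # per-voxel plateau inside the nucleus
    dapi_smooth_um: float = 0.5
    dapi_speckle: float = 0.1  # multiplicative speckle amplitude
    poisson_noise: bool = True
    read_noise_sd: float = 3.0  # additive Gaussian, photons; 0 disables
    n_clutter: int = 15  # extranuclear probe clutter per channel
    clutter_photons_range: Tuple[float, float] = (500.0, 3000.0)
    box_side_um: float = 45.0  # minimum nucleus bounding-box separation
    min_allele_separation_um: float = 3.0
    channels: Tuple[str, ...] = ("DAPI", "FITC", "TRITC")
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.p_int <= 1.0:
            raise ValueError("p_int must lie in [0, 1]")
        for name in (
            "interacting_scale_um",
            "spot_photons",
            "dapi_photons",
            "box_side_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.noninteracting_range_um
        if not 0 < lo <= hi:
            raise ValueError("non-interacting range must satisfy 0 < lo <= hi")
        # the two distance regimes must not blur into each other: the
        # half-normal effective support (4 sigma) must end below the
        # non-interacting lower bound
        if 4.0 * self.interacting_scale_um > lo:
            raise ValueError(
                "interacting-distance scale too large relative to the "
                "non-interacting lower bound"
            )
        if min(self.psf_sigma_um) <= 0:
            raise ValueError("psf sigmas must be positive")
        if min(self.nucleus_semiaxes_um) <= 0:
            raise ValueError("nucleus semi-axes must be positive")

    @property
    def geometry(self) -> StackGeometry:
        nx, ny, nz = self.field_shape
        dx, dy, dz = self.voxel_um
        return StackGeometry(nx, ny, nz, dx, dy, dz)


def peak_amplitude(photons: float, sigma_um: Sequence[float],
                   geometry: StackGeometry) -> float:
    """Peak per-voxel intensity of a spot with the given integrated photon
    count (3D Gaussian normalisation in voxel units)."""
    sig_vox = np.asarray(sigma_um) / geometry.voxel_um
    return photons / ((2.0 * np.pi) ** 1.5 * np.prod(sig_vox))


def photons_for_peak(peak: float, sigma_um: Sequence[float],
                     geometry: StackGeometry) -> float:
    """Inverse of :func:`peak_amplitude`."""
    sig_vox = np.asarray(sigma_um) / geometry.voxel_um
    return peak * (2.0 * np.pi) ** 1.5 * np.prod(sig_vox)


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass
class TrueNucleus:
    id: int
    center_um: np.ndarray  # (x, y, z)
    semiaxes_um: np.ndarray

    def contains(self, pos_um, scale: float = 1.0) -> bool:
        r = (np.asarray(pos_um) - self.center_um) / (self.semiaxes_um * scale)
        return float(np.sum(r * r)) <= 1.0


@dataclass
class TruePair:
    nucleus_id: int
    pair_index: int
    fitc_um: np.ndarray  # rendered FITC position
    tritc_true_um: np.ndarray  # physical TRITC locus (pre chromatic offset)
    tritc_rendered_um: np.ndarray  # position rendered in the TRITC channel
    distance_pre_um: float  # |tritc_true - fitc|
    distance_post_um: float  # |tritc_rendered - fitc|
    interacting: bool
    clipped: bool = False  # any spot rendered partially outside the field


@dataclass
class SimGroundTruth:
    """Everything the simulator knows: per-nucleus geometry, true spot
    positions and pairings, clutter positions, and the injected chromatic
    offset."""

    nuclei: List[TrueNucleus] = field(default_factory=list)
    pairs: List[TruePair] = field(default_factory=list)
    clutter: List[Tuple[str, np.ndarray]] = field(default_factory=list)
    chromatic_offset_um: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    seed: int = 0

    def pairs_of(self, nucleus_id: int) -> List[TruePair]:
        return [p for p in self.pairs if p.nucleus_id == nucleus_id]

    def spot_positions(self, channel: str) -> np.ndarray:
        """(n, 3) array of rendered spot positions for one channel."""
        if channel == "FITC":
            pts = [p.fitc_um for p in self.pairs]
        elif channel == "TRITC":
            pts = [p.tritc_rendered_um for p in self.pairs]
        else:
            raise KeyError(channel)
        return np.array(pts).reshape(-1, 3)

    def to_frames(self):
        """Ground truth as (nuclei, pairs) pandas DataFrames."""
        import pandas as pd

        nuc = pd.DataFrame(
            [
                {
                    "nucleus_id": n.id,
                    "cx_um": n.center_um[0],
                    "cy_um": n.center_um[1],
                    "cz_um": n.center_um[2],
                    "ax_um": n.semiaxes_um[0],
                    "ay_um": n.semiaxes_um[1],
                    "az_um": n.semiaxes_um[2],
                }
                for n in self.nuclei
            ]
        )
        pairs = pd.DataFrame(
            [
                {
                    "nucleus_id": p.nucleus_id,
                    "pair_index": p.pair_index,
                    "fitc_x_um": p.fitc_um[0],
                    "fitc_y_um": p.fitc_um[1],
                    "fitc_z_um": p.fitc_um[2],
                    "tritc_x_um": p.tritc_rendered_um[0],
                    "tritc_y_um": p.tritc_rendered_um[1],
                    "tritc_z_um": p.tritc_rendered_um[2],
                    "distance_pre_um": p.distance_pre_um,
                    "distance_post_um": p.distance_post_um,
                    "interacting": p.interacting,
                    "clipped": p.clipped,
                }
                for p in self.pairs
            ]
        )
        return nuc, pairs


# ---------------------------------------------------------------------------
# rendering


def render_spot(image: np.ndarray, pos_um, photons: float,
                sigma_um, geometry: StackGeometry,
                truncate: float = 5.0) -> bool:
    """Add one PSF-blurred spot to ``image`` in place.

    The spot is an anisotropic 3D Gaussian integrated over voxel extents
    (separable erf profile), so the added intensity equals ``photons`` up to
    truncation of the +-``truncate`` sigma rendering window.  Returns True
    when the window was clipped by the field border.
    """
    if photons < 0:
        raise ValueError("photons must be non-negative")
    if photons == 0:
        return False
    pos = np.asarray(pos_um, dtype=float)
    sig = np.asarray(sigma_um, dtype=float)
    pitch = geometry.voxel_um
    dims = np.array([geometry.nx, geometry.ny, geometry.nz])

    profiles = []
    clipped = False
    for ax in range(3):  # x, y, z
        half = truncate * sig[ax]
        lo = int(np.floor((pos[ax] - half) / pitch[ax]))
        hi = int(np.ceil((pos[ax] + half) / pitch[ax]))
        if lo < 0 or hi > dims[ax]:
            clipped = True
        lo = max(lo, 0)
        hi = min(hi, int(dims[ax]))
        if hi <= lo:
            return True  # fully outside the field along this axis
        edges = np.arange(lo, hi + 1) * pitch[ax]
        cdf = 0.5 * (1.0 + erf((edges - pos[ax]) / (_SQRT2 * sig[ax])))
        profiles.append((lo, hi, np.diff(cdf)))

    (x0, x1, wx), (y0, y1, wy), (z0, z1, wz) = profiles
    image[z0:z1, y0:y1, x0:x1] += (
        photons * wz[:, None, None] * wy[None, :, None] * wx[None, None, :]
    )
    return clipped


def _render_dapi(geometry: StackGeometry, nuclei: List[TrueNucleus],
                 params: SimParams, rng: np.random.Generator) -> np.ndarray:
    img = np.zeros(geometry.shape, dtype=np.float64)
    pitch = geometry.voxel_um
    for nuc in nuclei:
        c_vox = geometry.um_to_voxel(nuc.center_um)
        r_vox = nuc.semiaxes_um / pitch
        lo = np.maximum(np.floor(c_vox - r_vox - 2).astype(int), 0)
        hi = np.minimum(
            np.ceil(c_vox + r_vox + 3).astype(int),
            np.array([geometry.nx, geometry.ny, geometry.nz]),
        )
        zz, yy, xx = np.meshgrid(
            np.arange(lo[2], hi[2]), np.arange(lo[1], hi[1]),
            np.arange(lo[0], hi[0]), indexing="ij",
        )
        rx = (xx + 0.5 - (c_vox[0] + 0.5)) / r_vox[0]
        ry = (yy + 0.5 - (c_vox[1] + 0.5)) / r_vox[1]
        rz = (zz + 0.5 - (c_vox[2] + 0.5)) / r_vox[2]
        inside = rx * rx + ry * ry + rz * rz <= 1.0
        img[lo[2]:hi[2], lo[1]:hi[1], lo[0]:hi[0]] += (
            params.dapi_photons * inside
        )
    sig_vox = params.dapi_smooth_um / pitch
    img = ndimage.gaussian_filter(img, sigma=sig_vox[::-1])
    if params.dapi_speckle > 0:
        speckle = ndimage.gaussian_filter(
            rng.standard_normal(geometry.shape), sigma=2.0)
        # renormalise the smoothed field to unit variance before scaling
        speckle /= max(speckle.std(), 1e-12)
        img *= np.clip(1.0 + params.dapi_speckle * speckle, 0.0, None)
    return img


def _sample_in_ellipsoid(rng: np.random.Generator, center: np.ndarray,
                         semiaxes: np.ndarray, scale: float) -> np.ndarray:
    while True:
        u = rng.uniform(-1.0, 1.0, size=3)
        if np.sum(u * u) <= 1.0:
            return center + u * semiaxes * scale


def _random_direction(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    n = np.linalg.norm(v)
    while n < 1e-9:
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
    return v / n


def sample_pair_distance(rng: np.random.Generator, p_int: float,
                         interacting_scale_um: float = 0.12,
                         noninteracting_range_um=(0.5, 3.0)
                         ) -> Tuple[float, bool]:
    """Draw one true pair distance from the two-regime mixture.

    Interacting pairs (probability ``p_int``) follow a half-normal law;
    non-interacting pairs are uniform on the given range.  Returns the
    distance in μm and the interacting flag.
    """
    interacting = bool(rng.random() < p_int)
    if interacting:
        d = abs(rng.normal(0.0, interacting_scale_um))
    else:
        d = rng.uniform(*noninteracting_range_um)
    return d, interacting


def _place_nuclei(params: SimParams,
                  rng: np.random.Generator) -> List[TrueNucleus]:
    geom = params.geometry
    extent = geom.extent_um
    box = params.box_side_um
    slots_x = int(extent[0] // box)
    slots_y = int(extent[1] // box)
    if params.n_nuclei > slots_x * slots_y:
        raise PackingError(
            f"cannot place {params.n_nuclei} nuclei with {box} um box "
            f"separation in a {extent[0]:.0f} x {extent[1]:.0f} um field "
            f"({slots_x * slots_y} slots)"
        )
    slot_ids = rng.choice(slots_x * slots_y, size=params.n_nuclei,
                          replace=False)
    semi = np.asarray(params.nucleus_semiaxes_um)
    nuclei = []
    for nid, slot in enumerate(np.sort(slot_ids)):
        sx, sy = int(slot % slots_x), int(slot // slots_x)
        slot_center = np.array([(sx + 0.5) * box, (sy + 0.5) * box])
        # jitter the centre but keep the nucleus inside its own box
        margin = np.maximum(box / 2.0 - semi[:2] - 1.0, 0.0)
        jitter = rng.uniform(-1.0, 1.0, size=2) * np.minimum(margin, 2.0)
        cz = extent[2] / 2.0 + rng.uniform(-1.0, 1.0)
        axes = semi * np.clip(
            1.0 + params.semiaxis_jitter * rng.standard_normal(3), 0.7, 1.3)
        nuclei.append(TrueNucleus(
            id=nid,
            center_um=np.array([*(slot_center + jitter), cz]),
            semiaxes_um=axes,
        ))
    return nuclei


def _sample_pairs(nuc: TrueNucleus, params: SimParams,
                  rng: np.random.Generator) -> List[TruePair]:
    pairs: List[TruePair] = []
    anchors: List[np.ndarray] = []
    for k in range(params.spots_per_channel):
        for _ in range(2000):
            fitc = _sample_in_ellipsoid(rng, nuc.center_um,
                                        nuc.semiaxes_um, 0.9)
            if all(np.linalg.norm(fitc - a) >=
                   params.min_allele_separation_um for a in anchors):
                break
        else:
            raise RuntimeError(
                "could not place alleles with the requested separation; "
                "nucleus too small for min_allele_separation_um")
        anchors.append(fitc)
        d, interacting = sample_pair_distance(
            rng, params.p_int, params.interacting_scale_um,
            params.noninteracting_range_um)
        tritc = None
        for _ in range(500):
            cand = fitc + d * _random_direction(rng)
            if nuc.contains(cand):
                tritc = cand
                break
        if tritc is None:  # no room at this distance: shrink toward feasible
            d, interacting = abs(rng.normal(0, params.interacting_scale_um)), True
            for _ in range(500):
                cand = fitc + d * _random_direction(rng)
                if nuc.contains(cand):
                    tritc = cand
                    break
            if tritc is None:
                tritc = fitc.copy()
        rendered = tritc + np.asarray(params.chromatic_offset_um)
        pairs.append(TruePair(
            nucleus_id=nuc.id,
            pair_index=k,
            fitc_um=fitc,
            tritc_true_um=tritc,
            tritc_rendered_um=rendered,
            distance_pre_um=float(np.linalg.norm(tritc - fitc)),
            distance_post_um=float(np.linalg.norm(rendered - fitc)),
            interacting=interacting,
        ))
    return pairs


def simulate_fov(params: SimParams) -> Tuple[MultiChannelStack, SimGroundTruth]:
    """Render one simulated field of view and its ground truth.

    Deterministic: identical ``params`` (including ``seed``) give
    bit-identical stacks and ground truth.
    """
    params.validate()
    # independent streams so the ground truth is invariant to the choice
    # of rendered channels and to the noise settings
    rng = np.random.default_rng((params.seed, 0))  # geometry + truth
    rng_tex = np.random.default_rng((params.seed, 1))  # DAPI texture
    rng_noise = np.random.default_rng((params.seed, 2))  # shot/read noise
    geom = params.geometry

    nuclei = _place_nuclei(params, rng) if params.n_nuclei > 0 else []
    truth = SimGroundTruth(
        nuclei=nuclei,
        chromatic_offset_um=np.asarray(params.chromatic_offset_um, float),
        seed=params.seed,
    )

    dapi = _render_dapi(geom, nuclei, params, rng_tex) \
        if "DAPI" in params.channels else None
    fitc = np.full(geom.shape, params.background_photons, dtype=np.float64)
    tritc = np.full(geom.shape, params.background_photons, dtype=np.float64)

    for nuc in nuclei:
        for pair in _sample_pairs(nuc, params, rng):
            c1 = render_spot(fitc, pair.fitc_um, params.spot_photons,
                             params.psf_sigma_um, geom)
            c2 = render_spot(tritc, pair.tritc_rendered_um,
                             params.spot_photons, params.psf_sigma_um, geom)
            pair.clipped = c1 or c2
            truth.pairs.append(pair)

    # extranuclear probe clutter: bright junk outside every nucleus
    extent = geom.extent_um
    for channel, img in (("FITC", fitc), ("TRITC", tritc)):
        placed = 0
        attempts = 0
        while placed < params.n_clutter and attempts < 10000:
            attempts += 1
            pos = rng.uniform(0.0, 1.0, size=3) * extent
            if any(n.contains(pos, scale=1.15) for n in nuclei):
                continue
            photons = rng.uniform(*params.clutter_photons_range)
            render_spot(img, pos, photons, params.psf_sigma_um, geom)
            truth.clutter.append((channel, pos))
            placed += 1

    channels = {"DAPI": dapi, "FITC": fitc, "TRITC": tritc}
    channels = {k: v for k, v in channels.items()
                if k in params.channels and v is not None}
    if params.poisson_noise:
        for name in channels:
            channels[name] = rng_noise.poisson(
                channels[name]).astype(np.float64)
    if params.read_noise_sd > 0:
        for name in channels:
            channels[name] = channels[name] + rng_noise.normal(
                0.0, params.read_noise_sd, size=geom.shape)

    return MultiChannelStack(geometry=geom, channels=channels), truth


def params_to_json(params: SimParams) -> str:
    """Serialise simulation parameters (sidecar for written stacks)."""
    d = dataclasses.asdict(params)
    return json.dumps(d, indent=2, default=lambda o: list(o))


def noise_sd(params: SimParams) -> float:
    """Approximate per-voxel noise s.d. at the FITC/TRITC background level
    (Poisson at the background plus read noise, in photons)."""
    var = 0.0
    if params.poisson_noise:
        var += params.background_photons
    var += params.read_noise_sd ** 2
    return float(np.sqrt(var))
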