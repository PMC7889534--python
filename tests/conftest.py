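"""Shared fixtures: small simulated fields and ground-truth helpers.

All image fixtures are generated at test time from the seeded simulator;
sizes are scaled to single-nucleus fields so the suite stays fast while
exercising the full physics (PSF rendering, Poisson + read noise,
chromatic offset, clutter).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from fishdist.geometry import StackGeometry
from fishdist.segment import NucleusMask, SegmentationParams, normalize_stack
from fishdist.synth import (SimParams, SimGroundTruth, noise_sd,
                            photons_for_peak, simulate_fov)


def single_nucleus_params(**overrides) -> SimParams:
    """One nucleus in a compact field, FITC/TRITC only (detection-scale)."""
    defaults = dict(
        field_shape=(170, 170, 42),
        n_nuclei=1,
        box_side_um=18.0,
        channels=("FITC", "TRITC"),
        n_clutter=5,
    )
    defaults.update(overrides)
    return SimParams(**defaults)


def with_peak_snr(params: SimParams, snr: float) -> SimParams:
    """Set the spot brightness to ``snr`` x the per-voxel noise s.d."""
    photons = photons_for_peak(snr * noise_sd(params), params.psf_sigma_um,
                               params.geometry)
    return dataclasses.replace(params, spot_photons=photons)


def true_ellipsoid_mask(truth: SimGroundTruth, geometry: StackGeometry,
                        nucleus_index: int = 0) -> NucleusMask:
    """Ground-truth nucleus mask (analytic ellipsoid), for tests that
    isolate detection/pairing from segmentation."""
    nuc = truth.nuclei[nucleus_index]
    zz, yy, xx = np.meshgrid(*(np.arange(n) for n in geometry.shape),
                             indexing="ij")
    pos = np.stack([(xx + 0.5) * geometry.dx, (yy + 0.5) * geometry.dy,
                    (zz + 0.5) * geometry.dz], axis=-1)
    r = (pos - nuc.center_um) / nuc.semiaxes_um
    mask = (r ** 2).sum(axis=-1) <= 1.0
    return NucleusMask(nuc.id, (0, geometry.nz, 0, geometry.ny,
                                0, geometry.nx), mask,
                       float(mask.sum()) * geometry.voxel_volume_um3)


def match_detections_to_truth(dets, true_positions, radius_um=0.5):
    """For each true position, index of the nearest detection within
    ``radius_um`` (or None)."""
    out = []
    for tp in np.atleast_2d(true_positions):
        if not dets:
            out.append(None)
            continue
        d = [np.linalg.norm(np.asarray(det.pos_um) - tp) for det in dets]
        k = int(np.argmin(d))
        out.append(k if d[k] < radius_um else None)
    return out


@pytest.fixture(scope="session")
def small_field_run():
    """Two simulated 4-nucleus FOVs pushed through the full pipeline.

    Field and box sizes are scaled down (20 μm boxes) so the fixture
    builds in seconds; all pipeline stages run at their defaults
    otherwise.
    """
    import tempfile

    from fishdist.pipeline import PipelineConfig, run_pipeline

    stacks, truths = {}, {}
    for k in range(2):
        p = SimParams(field_shape=(400, 400, 50), n_nuclei=4,
                      box_side_um=20.0, seed=40 + k)
        stacks[f"slideA_fov{k}"], truths[f"slideA_fov{k}"] = simulate_fov(p)
    cfg = PipelineConfig(
        segmentation=SegmentationParams(box_side_um=20.0),
        outdir=tempfile.mkdtemp(prefix="fishdist_e2e_"),
    )
    manifest = run_pipeline(cfg, stacks=stacks)
    return {"stacks": stacks, "truths": truths, "config": cfg,
            "manifest": manifest}
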