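"""Normalisation, seed finding, 3D segmentation and nucleus filtering."""

import dataclasses

import numpy as np
import pytest
from skimage.filters import threshold_otsu

from fishdist.geometry import MultiChannelStack, StackGeometry
from fishdist.segment import (NucleusMask, SegmentationParams,
                              filter_nuclei, find_nucleus_seeds,
                              normalize_stack, segment_field,
                              segment_nucleus_3d)
from fishdist.synth import SimParams, TrueNucleus, _render_dapi, simulate_fov


def _stack_of(arr):
    nz, ny, nx = arr.shape
    return MultiChannelStack(StackGeometry(nx, ny, nz),
                             {"DAPI": arr.astype(float)})


class TestNormalize:
    def test_affine_map_to_unit_range(self):
        s = _stack_of(np.array([[[2.0, 4.0, 6.0]]]))
        out = normalize_stack(s)["DAPI"]
        np.testing.assert_allclose(out, [[[0.0, 0.5, 1.0]]])

    def test_constant_channel_maps_to_zero(self):
        s = _stack_of(np.full((2, 3, 3), 7.0))
        assert not normalize_stack(s)["DAPI"].any()

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        s = _stack_of(rng.uniform(10, 90, size=(4, 8, 8)))
        once = normalize_stack(s)
        twice = normalize_stack(once)
        np.testing.assert_allclose(twice["DAPI"], once["DAPI"])

    def test_invariant_to_global_affine_rescaling(self):
        rng = np.random.default_rng(1)
        raw = rng.uniform(0, 100, size=(4, 8, 8))
        a = normalize_stack(_stack_of(raw))["DAPI"]
        b = normalize_stack(_stack_of(3.5 * raw + 12.0))["DAPI"]
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_nonfinite_voxels_rejected(self):
        arr = np.ones((2, 3, 3))
        arr[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            normalize_stack(_stack_of(arr))


def _dapi_field(nuclei_centers_um, shape=(500, 500, 40), seed=0):
    """Noise-free DAPI field with nuclei at given (x, y, z) centres."""
    params = SimParams(field_shape=shape, dapi_speckle=0.0)
    geom = params.geometry
    nuclei = [TrueNucleus(i, np.asarray(c, float), np.array([7.0, 5.0, 2.5]))
              for i, c in enumerate(nuclei_centers_um)]
    rng = np.random.default_rng(seed)
    dapi = _render_dapi(geom, nuclei, params, rng)
    return dapi / dapi.max() if dapi.max() > 0 else dapi, geom, nuclei


class TestSeeds:
    def test_blank_image_yields_no_seeds(self):
        dapi, geom, _ = _dapi_field([])
        assert find_nucleus_seeds(dapi, geom,
                                  SegmentationParams(box_side_um=45.0)) == []

    def test_single_nucleus_seed_centred_on_centroid(self):
        center = (27.0, 26.0, 5.8)
        dapi, geom, _ = _dapi_field([center])
        boxes = find_nucleus_seeds(dapi, geom,
                                   SegmentationParams(box_side_um=45.0))
        assert len(boxes) == 1
        cx, cy = boxes[0].center_xy_vox
        # within one filtered-image pixel of the projected centroid
        assert abs((cx + 0.5) * geom.dx - center[0]) <= 2 * geom.dx
        assert abs((cy + 0.5) * geom.dy - center[1]) <= 2 * geom.dy

    def test_two_close_nuclei_discard_both_boxes(self):
        # 15 μm apart: each 45 μm box captures both maxima -> zero seeds
        dapi, geom, _ = _dapi_field([(20.0, 27.0, 5.8), (35.0, 27.0, 5.8)])
        boxes = find_nucleus_seeds(dapi, geom,
                                   SegmentationParams(box_side_um=45.0))
        assert boxes == []


@pytest.fixture(scope="module")
def noise_free():
    params = SimParams(field_shape=(230, 230, 48), n_nuclei=1,
                       box_side_um=20.0, seed=11, poisson_noise=False,
                       read_noise_sd=0.0, dapi_speckle=0.0)
    stack, truth = simulate_fov(params)
    return normalize_stack(stack), truth


class TestSegment3D:
    def test_noise_free_iou_against_true_ellipsoid(self, noise_free):
        norm, truth = noise_free
        geom = norm.geometry
        sp = SegmentationParams(box_side_um=20.0)
        accepted, _ = segment_field(norm["DAPI"], geom, sp)
        assert len(accepted) == 1
        full = accepted[0].full_mask(geom)
        nuc = truth.nuclei[0]
        zz, yy, xx = np.meshgrid(*(np.arange(n) for n in geom.shape),
                                 indexing="ij")
        pos = np.stack([(xx + 0.5) * geom.dx, (yy + 0.5) * geom.dy,
                        (zz + 0.5) * geom.dz], axis=-1)
        true = ((pos - nuc.center_um) / nuc.semiaxes_um)
        true = (true ** 2).sum(axis=-1) <= 1.0
        iou = (full & true).sum() / (full | true).sum()
        assert iou >= 0.8

    def test_global_refinement_rule_holds(self, noise_free):
        """No mask voxel may be dimmer than 0.6 x the global threshold."""
        norm, _ = noise_free
        geom = norm.geometry
        sp = SegmentationParams(box_side_um=20.0)
        boxes = find_nucleus_seeds(norm["DAPI"], geom, sp)
        mask = segment_nucleus_3d(norm["DAPI"], boxes[0], geom, sp)
        z0, z1, y0, y1, x0, x1 = mask.bbox
        sub = norm["DAPI"][z0:z1, y0:y1, x0:x1]
        t_global = threshold_otsu(sub)
        assert sub[mask.mask].min() >= sp.global_factor * t_global

    def test_blank_box_rejected_with_reason(self):
        dapi, geom, _ = _dapi_field([], shape=(200, 200, 20))
        from fishdist.segment import SeedBox

        box = SeedBox((100, 100), 50, 150, 50, 150)
        mask = segment_nucleus_3d(dapi, box, geom, SegmentationParams())
        assert not mask.accepted and mask.reason == "empty"


class TestFilter:
    def _mask(self, geom, x0=10, vol_vox=2000, mid=True):
        m = np.zeros((geom.nz, 20, 20), dtype=bool)
        m[geom.nz // 2, 5:15, 5:15] = True
        extra = vol_vox - int(m.sum())
        if extra > 0:
            m[geom.nz // 2 + 1].flat[:extra] = True
        return NucleusMask(0, (0, geom.nz, 40, 60, x0, x0 + 20), m,
                           float(m.sum()) * geom.voxel_volume_um3)

    def test_border_touching_rejected(self):
        geom = StackGeometry(100, 100, 12)
        m = self._mask(geom, x0=0)
        m.mask[:, :, 0] = m.mask[:, :, 5]  # push voxels onto x=0
        accepted, rejected = filter_nuclei([m], SegmentationParams(), geom)
        assert not accepted and rejected[0].reason == "border"

    def test_volume_bounds_enforced(self):
        geom = StackGeometry(100, 100, 12)
        small = self._mask(geom, vol_vox=120)  # far below 200 um^3
        accepted, rejected = filter_nuclei([small], SegmentationParams(),
                                           geom)
        assert not accepted and rejected[0].reason == "volume"

    def test_z_border_not_penalised(self):
        """Stacks over-range in z; only lateral borders reject."""
        geom = StackGeometry(100, 100, 12)
        m = self._mask(geom)
        m.mask[0] = m.mask[geom.nz // 2]  # touches the z=0 face
        vol = float(m.mask.sum()) * geom.voxel_volume_um3
        m.volume_um3 = max(vol, 250.0)
        accepted, _ = filter_nuclei([m], SegmentationParams(
            volume_bounds_um3=(0.1, 4000.0)), geom)
        assert len(accepted) == 1


class TestOnSimulatedFields:
    def test_all_well_placed_nuclei_recovered(self, small_field_run):
        """Accepted-mask count equals ground truth on well-separated
        fields with moderate noise."""
        n_true = sum(len(t.nuclei)
                     for t in small_field_run["truths"].values())
        n_acc = small_field_run["manifest"].totals["nuclei_accepted"]
        assert n_acc >= 0.95 * n_true

    def test_masks_pairwise_disjoint(self, small_field_run):
        from fishdist.pipeline import process_fov

        name, stack = next(iter(small_field_run["stacks"].items()))
        res = process_fov(stack, small_field_run["config"], name)
        total = np.zeros(stack.geometry.shape, dtype=np.int32)
        for m in res["masks"]:
            total += m.full_mask(stack.geometry)
        assert total.max() <= 1
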