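"""ROI cropping and PCA-based standard-plane recovery."""

import warnings

import numpy as np
import pytest

from contraplane import (
    CylinderMaskSpec,
    VolumeGrid,
    crop_roi,
    derive_plane_params,
    estimate_frame,
    estimate_planes,
    make_plane_cylinder_masks,
)
from contraplane.errors import (
    EigenvalueDegeneracyWarning,
    InsufficientForegroundError,
    MissingClassError,
)
from contraplane.geometry import StandardPlaneFrame, rotation_matrix, voxel_to_world
from contraplane.masks import PlaneLabelVolume
from contraplane.metrics import frame_errors
from contraplane.nn.oracle import apply_label_noise, oracle_plane_segmenter

from conftest import random_frame


class TestCropRoi:
    def test_full_size_center_crop_is_identity(self, unilateral_sample):
        vol = unilateral_sample.volume
        roi = crop_roi(vol, vol.grid.center_mm, vol.grid.shape[0])
        assert roi.offset_voxels == (0, 0, 0)
        assert np.array_equal(roi.volume.values, vol.values)
        assert not roi.pad_mask.any()

    def test_boundary_crop_pads_and_records(self, unilateral_sample):
        vol = unilateral_sample.volume
        center = voxel_to_world((5, 32, 32), vol.grid)
        roi = crop_roi(vol, center, 48)
        assert roi.pad_mask[:19].all() and not roi.pad_mask[19:].any()
        assert np.all(roi.volume.values[roi.pad_mask] == 0)

    def test_world_coordinates_preserved(self, unilateral_sample, rng):
        vol = unilateral_sample.volume
        roi = crop_roi(vol, vol.grid.center_mm + 7.0, 32)
        for _ in range(20):
            ijk = rng.integers(0, 32, size=3)
            parent = np.asarray(roi.offset_voxels) + ijk
            np.testing.assert_allclose(
                voxel_to_world(ijk, roi.volume.grid), voxel_to_world(parent, vol.grid), atol=1e-9
            )

    def test_center_outside_grid_rejected(self, unilateral_sample):
        with pytest.raises(ValueError):
            crop_roi(unilateral_sample.volume, (-500.0, 0.0, 0.0), 32)


def _single_cylinder_mask(grid, normal, center, radius, height):
    coords = grid.world_coordinates() - np.asarray(center)
    proj = coords @ normal
    radial2 = (coords**2).sum(-1) - proj**2
    return (np.abs(proj) <= height / 2) & (radial2 <= radius**2)


class TestDerivePlaneParams:
    def test_axis_aligned_cylinder(self):
        grid = VolumeGrid((61, 61, 61))
        z = np.array([0.0, 0.0, 1.0])
        mask = _single_cylinder_mask(grid, z, (30.0, 30.0, 30.0), 25.0, 2.0)
        normal, centroid, eigvals = derive_plane_params(mask, grid, z)
        ang = np.degrees(np.arccos(abs(normal @ z)))
        assert ang < 0.5
        np.testing.assert_allclose(centroid, (30.0, 30.0, 30.0), atol=0.1)
        assert eigvals[0] == pytest.approx(eigvals[1], rel=0.02)
        assert eigvals[2] < eigvals[1] / 10

    def test_rotated_cylinder_recovers_rotated_axis(self):
        grid = VolumeGrid((61, 61, 61))
        axis = rotation_matrix((30.0, 0.0, 0.0)) @ np.array([0.0, 0.0, 1.0])
        mask = _single_cylinder_mask(grid, axis, (30.0, 30.0, 30.0), 25.0, 2.0)
        normal, _, _ = derive_plane_params(mask, grid, axis)
        assert np.degrees(np.arccos(abs(normal @ axis))) < 1.0

    def test_omitted_cross_bars_do_not_bias(self):
        # the intersection bars removed from the training masks are symmetric
        # about the plane: PCA normal and centroid barely move
        grid = VolumeGrid((61, 61, 61))
        frame = StandardPlaneFrame((30.0, 30.0, 30.0), (1, 0, 0), (0, 1, 0), (0, 0, 1))
        lv = make_plane_cylinder_masks(CylinderMaskSpec(frame, 25.0, 2.0), grid)
        for k, n_true in [(1, frame.n_sag), (2, frame.n_ax), (3, frame.n_cor)]:
            normal, centroid, _ = derive_plane_params(lv.labels == k, grid, n_true)
            assert np.degrees(np.arccos(abs(np.clip(normal @ n_true, -1, 1)))) < 1.0
            assert np.linalg.norm(centroid - frame.intersection_mm) < 0.5

    def test_enumeration_order_invariance(self, rng):
        grid = VolumeGrid((31, 31, 31))
        mask = rng.random((31, 31, 31)) > 0.9
        a = derive_plane_params(mask, grid)
        b = derive_plane_params(np.ascontiguousarray(mask[::1]), grid)
        np.testing.assert_allclose(a[0], b[0], atol=0)

    def test_too_few_voxels_rejected(self):
        grid = VolumeGrid((16, 16, 16))
        mask = np.zeros((16, 16, 16), dtype=bool)
        mask[4:6, 4:6, 4] = True
        with pytest.raises(InsufficientForegroundError):
            derive_plane_params(mask, grid)

    def test_degenerate_eigengap_warns(self):
        grid = VolumeGrid((21, 21, 21))
        mask = np.zeros((21, 21, 21), dtype=bool)
        mask[2:19, 2:19, 2:19] = True  # near-isotropic blob: no plane direction
        with pytest.warns(EigenvalueDegeneracyWarning):
            derive_plane_params(mask, grid)


class TestEstimateFrame:
    def test_round_trip_from_generated_masks(self, rng):
        grid = VolumeGrid((72, 72, 72))
        frame = random_frame(rng, box_mm=(30.0, 42.0))
        lv = make_plane_cylinder_masks(CylinderMaskSpec(frame, 25.0, 2.0), grid)
        est = estimate_frame(lv, reference=frame)
        err = frame_errors(est.frame, frame)
        assert max(err.ang_sag_deg, err.ang_ax_deg, err.ang_cor_deg) < 1.0
        assert err.pos_mm < 1.0

    def test_five_percent_label_noise_stays_within_tolerance(self, rng):
        grid = VolumeGrid((72, 72, 72))
        frame = random_frame(rng, box_mm=(30.0, 42.0))
        lv = make_plane_cylinder_masks(CylinderMaskSpec(frame, 25.0, 2.0), grid)
        noisy = apply_label_noise(lv.labels, 0.05, np.random.default_rng(0))
        est = estimate_frame(PlaneLabelVolume(grid, noisy), reference=frame)
        err = frame_errors(est.frame, frame)
        assert max(err.ang_sag_deg, err.ang_ax_deg, err.ang_cor_deg) < 3.0
        assert err.pos_mm < 1.5

    def test_missing_class_names_the_class(self):
        grid = VolumeGrid((48, 48, 48))
        frame = StandardPlaneFrame((24.0, 24.0, 24.0), (1, 0, 0), (0, 1, 0), (0, 0, 1))
        lv = make_plane_cylinder_masks(CylinderMaskSpec(frame, 18.0, 2.0), grid)
        labels = lv.labels.copy()
        labels[labels == 2] = 0
        with pytest.raises(MissingClassError) as excinfo:
            estimate_frame(PlaneLabelVolume(grid, labels))
        assert excinfo.value.class_name == "axial"

    def test_intersection_of_symmetric_cross_within_half_voxel(self):
        grid = VolumeGrid((61, 61, 61))
        frame = StandardPlaneFrame((30.0, 30.0, 30.0), (1, 0, 0), (0, 1, 0), (0, 0, 1))
        lv = make_plane_cylinder_masks(CylinderMaskSpec(frame, 20.0, 2.0), grid)
        est = estimate_frame(lv, reference=frame)
        assert np.linalg.norm(est.frame.intersection_mm - frame.intersection_mm) <= 0.5


class TestEstimatePlanes:
    def test_oracle_segmenter_round_trip_on_phantom(self, unilateral_sample):
        truth = unilateral_sample.frames[0]
        roi = crop_roi(unilateral_sample.volume, truth.intersection_mm, 48)
        est = estimate_planes(roi, oracle_plane_segmenter(unilateral_sample), reference=truth)
        err = frame_errors(est.frame, truth)
        assert max(err.ang_sag_deg, err.ang_ax_deg, err.ang_cor_deg) < 1.0
        assert err.pos_mm < 1.0

    def test_label_noise_median_over_seeds(self, unilateral_sample):
        truth = unilateral_sample.frames[0]
        roi = crop_roi(unilateral_sample.volume, truth.intersection_mm, 48)
        errs = []
        for seed in range(10):
            seg = oracle_plane_segmenter(unilateral_sample, noise_rate=0.10, seed=seed)
            est = estimate_planes(roi, seg, reference=truth)
            e = frame_errors(est.frame, truth)
            errs.append(max(e.ang_sag_deg, e.ang_ax_deg, e.ang_cor_deg))
        assert np.median(errs) < 4.0

    def test_clipped_roi_still_returns_estimate(self, unilateral_sample):
        # ROI too small for the full 30 mm cylinders: estimate degrades but returns
        truth = unilateral_sample.frames[0]
        roi = crop_roi(unilateral_sample.volume, truth.intersection_mm, 24)
        seg = oracle_plane_segmenter(unilateral_sample, radius_mm=30.0, height_mm=2.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", EigenvalueDegeneracyWarning)
            est = estimate_planes(roi, seg, reference=truth, min_voxels=20)
        assert est.frame is not None

    def test_rotation_equivariance_of_voxelized_recovery(self, rng):
        grid = VolumeGrid((72, 72, 72))
        base = random_frame(rng, box_mm=(32.0, 40.0))
        est_base = estimate_frame(
            make_plane_cylinder_masks(CylinderMaskSpec(base, 25.0, 2.0), grid), reference=base
        )
        for _ in range(3):
            from conftest import random_rotation

            rot = random_rotation(rng)
            rotated = base.transformed(rot, translation=base.intersection_mm - rot @ base.intersection_mm)
            est_rot = estimate_frame(
                make_plane_cylinder_masks(CylinderMaskSpec(rotated, 25.0, 2.0), grid),
                reference=rotated,
            )
            for name in ("n_sag", "n_ax", "n_cor"):
                expected = rot @ getattr(est_base.frame, name)
                got = getattr(est_rot.frame, name)
                ang = np.degrees(np.arccos(np.clip(abs(expected @ got), 0, 1)))
                assert ang < 1.5
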