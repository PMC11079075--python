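"""Overlap and surface-distance metrics against exhaustive oracles."""

import numpy as np
import pytest

from cbctseg import (
    LabelVolume,
    aggregate_reports,
    average_surface_distance,
    dice_score,
    evaluate_case,
    extract_surface,
    fdi_to_position,
    hausdorff_distance,
    iou_score,
    miou,
)
from cbctseg.phantom import perturb_labels
from cbctseg.volume import CbctError, GridMismatchError
from conftest import random_blob_mask


def label_volume(arr, spacing=(1.0, 1.0, 1.0)):
    return LabelVolume(np.asarray(arr, np.int32), spacing)


def oracle_surface(mask):
    """Naive surface definition: mask voxel with a 6-neighbour outside."""
    mask = np.asarray(mask, bool)
    out = []
    for idx in np.argwhere(mask):
        for axis in range(3):
            for step in (-1, 1):
                n = idx.copy()
                n[axis] += step
                if (
                    n[axis] < 0
                    or n[axis] >= mask.shape[axis]
                    or not mask[tuple(n)]
                ):
                    out.append(tuple(idx))
                    break
            else:
                continue
            break
    return np.array(sorted(set(out)))


def oracle_distances(a_mask, b_mask, spacing):
    """All-pairs surface distances: directed nearest for each side."""
    sp = np.asarray(spacing)
    a = oracle_surface(a_mask) * sp
    b = oracle_surface(b_mask) * sp
    d = np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(-1))
    return d.min(axis=1), d.min(axis=0)


class TestOverlap:
    def test_identical_masks(self):
        vol = label_volume(np.random.default_rng(0).integers(0, 2, (5, 5, 5)))
        assert dice_score(vol, vol, 1) == 1.0
        assert iou_score(vol, vol, 1) == 1.0

    def test_half_overlap(self):
        a = np.zeros((1, 1, 4), int)
        b = np.zeros((1, 1, 4), int)
        a[0, 0, :2] = 1
        b[0, 0, 1:3] = 1
        assert dice_score(label_volume(a), label_volume(b), 1) == 0.5
        assert iou_score(label_volume(a), label_volume(b), 1) == pytest.approx(1 / 3)

    def test_disjoint_masks(self):
        a = np.zeros((1, 1, 4), int)
        b = np.zeros((1, 1, 4), int)
        a[0, 0, 0] = 1
        b[0, 0, 3] = 1
        assert dice_score(label_volume(a), label_volume(b), 1) == 0.0

    def test_both_empty_is_vacuous(self):
        empty = label_volume(np.zeros((3, 3, 3), int))
        value, vacuous = dice_score(empty, empty, 1, return_flag=True)
        assert value == 1.0 and vacuous

    def test_miou_bounded_by_mean_dice(self):
        rng = np.random.default_rng(1)
        a = label_volume(rng.integers(0, 3, (6, 6, 6)))
        b = label_volume(rng.integers(0, 3, (6, 6, 6)))
        mean_dice = np.mean([dice_score(a, b, c) for c in (1, 2)])
        assert miou(a, b, [1, 2]) <= mean_dice + 1e-12

    def test_empty_class_list_rejected(self):
        vol = label_volume(np.ones((2, 2, 2), int))
        with pytest.raises(CbctError):
            miou(vol, vol, [])

    def test_grid_mismatch_rejected(self):
        a = label_volume(np.ones((2, 2, 2), int))
        b = label_volume(np.ones((2, 2, 3), int))
        with pytest.raises(GridMismatchError):
            dice_score(a, b, 1)


class TestSurface:
    def test_single_voxel_is_its_own_surface(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 1, 1] = True
        np.testing.assert_array_equal(extract_surface(mask), [[1, 1, 1]])

    def test_solid_cube_has_26_surface_voxels(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[1:4, 1:4, 1:4] = True
        assert len(extract_surface(mask)) == 26

    def test_thin_slab_is_all_surface(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[2] = True
        assert len(extract_surface(mask)) == 16

    def test_boundary_counts_as_background(self):
        mask = np.ones((3, 3, 3), bool)
        assert len(extract_surface(mask)) == 26  # only the center is interior

    def test_empty_mask_rejected(self):
        with pytest.raises(CbctError):
            extract_surface(np.zeros((2, 2, 2), bool))


class TestDistances:
    def test_identical_masks_zero(self):
        mask = np.zeros((4, 4, 4), bool)
        mask[1:3, 1:3, 1:3] = True
        assert hausdorff_distance(mask, mask, (0.4, 0.4, 0.4)) == 0.0
        assert average_surface_distance(mask, mask, (0.4, 0.4, 0.4)) == 0.0

    def test_single_voxels_five_apart(self):
        a = np.zeros((8, 1, 1), bool)
        b = np.zeros((8, 1, 1), bool)
        a[1], b[6] = True, True
        assert hausdorff_distance(a, b, (0.4, 0.4, 0.4)) == pytest.approx(2.0)

    def test_parallel_planes(self):
        a = np.zeros((6, 4, 4), bool)
        b = np.zeros((6, 4, 4), bool)
        a[1], b[3] = True, True
        assert average_surface_distance(a, b, (0.25, 0.25, 0.25)) == pytest.approx(0.5)

    def test_empty_side_named(self):
        mask = np.ones((2, 2, 2), bool)
        with pytest.raises(CbctError, match="ground-truth"):
            hausdorff_distance(mask, np.zeros((2, 2, 2), bool), (1, 1, 1))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_allpairs_oracle(self, seed):
        """HD/ASD equal exhaustive all-pairs computation, anisotropic mm."""
        rng = np.random.default_rng(seed)
        spacing = (0.4, 0.5, 0.3)
        a = random_blob_mask(rng, (8, 9, 10))
        b = random_blob_mask(rng, (8, 9, 10))
        d_ab, d_ba = oracle_distances(a, b, spacing)
        hd_oracle = max(d_ab.max(), d_ba.max())
        asd_oracle = np.concatenate([d_ab, d_ba]).mean()
        assert hausdorff_distance(a, b, spacing) == pytest.approx(hd_oracle, abs=1e-9)
        assert average_surface_distance(a, b, spacing) == pytest.approx(
            asd_oracle, abs=1e-9
        )

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a = random_blob_mask(rng, (7, 7, 7))
        b = random_blob_mask(rng, (7, 7, 7))
        sp = (0.4, 0.4, 0.4)
        assert hausdorff_distance(a, b, sp) == hausdorff_distance(b, a, sp)
        assert average_surface_distance(a, b, sp) == average_surface_distance(b, a, sp)

    def test_rigid_translation_invariance(self):
        rng = np.random.default_rng(6)
        a = random_blob_mask(rng, (6, 6, 6))
        b = random_blob_mask(rng, (6, 6, 6))
        big_a = np.zeros((10, 10, 10), bool)
        big_b = np.zeros((10, 10, 10), bool)
        big_a[:6, :6, :6], big_b[:6, :6, :6] = a, b
        shifted_a = np.roll(big_a, (2, 3, 1), axis=(0, 1, 2))
        shifted_b = np.roll(big_b, (2, 3, 1), axis=(0, 1, 2))
        sp = (0.4, 0.4, 0.4)
        assert hausdorff_distance(shifted_a, shifted_b, sp) == pytest.approx(
            hausdorff_distance(big_a, big_b, sp)
        )


class TestFdiMapping:
    @pytest.mark.parametrize(
        "code,position",
        [(11, "T1"), (21, "T1"), (36, "T6"), (48, "T8"), (25, "T5")],
    )
    def test_valid_codes(self, code, position):
        assert fdi_to_position(code) == position

    @pytest.mark.parametrize("code", [49, 19, 50, 10, 0, 99])
    def test_invalid_codes(self, code):
        with pytest.raises(CbctError):
            fdi_to_position(code)


class TestEvaluateCase:
    def test_identity_is_perfect(self, small_phantom):
        _, labels = small_phantom
        report = evaluate_case(labels, labels)
        for cm in report.per_class.values():
            assert cm.dice == 1.0 and cm.iou == 1.0
            assert cm.hd == 0.0 and cm.asd == 0.0
        assert all(v == 1.0 for v in report.per_position.values())

    def test_missing_tooth_flagged(self, small_phantom):
        _, labels = small_phantom
        pred = labels.values.copy()
        pred[pred == 36] = 2  # drop tooth 36 into the mandible class
        report = evaluate_case(label_volume(pred, labels.spacing), labels)
        cm = report.per_tooth[36]
        assert cm.dice == 0.0 and cm.status == "missing-pred"
        assert cm.hd is None and cm.asd is None

    def test_dilated_prediction_asd_below_spacing(self, small_phantom):
        _, labels = small_phantom
        pred = perturb_labels(labels, "dilate", 1)
        report = evaluate_case(pred, labels)
        spacing = max(labels.spacing)
        for name, cm in report.per_class.items():
            if cm.status == "ok":
                assert cm.asd <= spacing, name


class TestAggregate:
    def test_single_report_has_zero_std(self, small_phantom):
        _, labels = small_phantom
        tables = aggregate_reports([evaluate_case(labels, labels)])
        classes = tables["classes"]
        assert (classes.loc["teeth", "dice_std"]) == 0.0
        assert classes.loc["teeth", "dice_mean"] == 100.0

    def test_two_report_sample_std(self):
        from cbctseg import ClassMetrics, MetricReport

        a = MetricReport(per_class={"teeth": ClassMetrics(0.9, 0.8, 1.0, 0.1, "ok")})
        b = MetricReport(per_class={"teeth": ClassMetrics(1.0, 1.0, 0.0, 0.0, "ok")})
        tables = aggregate_reports([a, b])
        assert tables["classes"].loc["teeth", "dice_mean"] == pytest.approx(95.0)
        assert tables["classes"].loc["teeth", "dice_std"] == pytest.approx(
            7.07, abs=0.01
        )

    def test_column_order(self, small_phantom):
        _, labels = small_phantom
        tables = aggregate_reports([evaluate_case(labels, labels)])
        display_cols = [c for c in tables["classes"].columns if "/" in c]
        assert display_cols == ["Dice/%", "mIoU/%", "HD/mm", "ASD/mm"]

    def test_empty_list_rejected(self):
        with pytest.raises(CbctError):
            aggregate_reports([])
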