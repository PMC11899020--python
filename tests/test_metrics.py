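"""Confusion-based region metrics, Hausdorff distance, and Cohen's kappa."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from _oracles import (brute_force_hausdorff, confusion_from_masks,
                      kappa_by_hand, set_metrics)
from cervseg.losses import dice_loss
from cervseg.metrics import (ConfusionCounts, EmptyMaskError,
                             accumulate_confusion, boundary_pixels,
                             cohens_kappa, dice_coefficient, evaluate_dataset,
                             fw_iou, hausdorff_distance, mean_iou,
                             mean_pixel_accuracy, MetricReport, pixel_accuracy)

HAND = ConfusionCounts(np.array([[2, 0], [1, 1]]))


class TestConfusion:
    def test_diagonal_case(self):
        m = np.zeros((8, 8), np.uint8)
        m[:2, :5] = 1
        c = accumulate_confusion(m, m)
        assert np.array_equal(c.p, [[54, 0], [0, 10]])

    def test_hand_count(self):
        c = accumulate_confusion(np.array([[0, 1, 1, 0]]), np.array([[0, 1, 0, 0]]))
        assert np.array_equal(c.p, [[2, 0], [1, 1]])

    def test_accumulation_commutes(self, rng):
        a1, p1 = rng.random((6, 6)) > 0.5, rng.random((6, 6)) > 0.5
        a2, p2 = rng.random((6, 6)) > 0.4, rng.random((6, 6)) > 0.6
        ab = accumulate_confusion(a2, p2, accumulate_confusion(a1, p1))
        ba = accumulate_confusion(a1, p1, accumulate_confusion(a2, p2))
        assert np.array_equal(ab.p, ba.p)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            accumulate_confusion(np.zeros((3, 3)), np.zeros((4, 4)))

    def test_matches_set_oracle(self, rng):
        t, p = rng.random((9, 9)) > 0.6, rng.random((9, 9)) > 0.3
        assert np.array_equal(accumulate_confusion(t, p).p, confusion_from_masks(t, p))


class TestRegionMetrics:
    def test_hand_values(self):
        assert pixel_accuracy(HAND) == 0.75
        assert mean_pixel_accuracy(HAND) == 0.75
        assert mean_iou(HAND) == pytest.approx(7 / 12)
        assert fw_iou(HAND) == pytest.approx(7 / 12)
        assert dice_coefficient(HAND) == pytest.approx(2 / 3)

    def test_perfect_prediction_all_ones(self):
        c = ConfusionCounts(np.array([[40, 0], [0, 24]]))
        for metric in (pixel_accuracy, mean_pixel_accuracy, mean_iou, fw_iou,
                       dice_coefficient):
            assert metric(c) == 1.0

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            pixel_accuracy(ConfusionCounts())

    @pytest.mark.parametrize("seed", range(25))
    def test_random_masks_match_set_oracle(self, seed):
        r = np.random.default_rng(seed)
        t = r.random((5, 5)) > r.uniform(0.2, 0.8)
        p = r.random((5, 5)) > r.uniform(0.2, 0.8)
        c = accumulate_confusion(t, p)
        want = set_metrics(t, p)
        assert pixel_accuracy(c) == pytest.approx(want["pa"], abs=1e-12)
        assert mean_pixel_accuracy(c) == pytest.approx(want["mpa"], abs=1e-12)
        assert mean_iou(c) == pytest.approx(want["miou"], abs=1e-12)
        assert fw_iou(c) == pytest.approx(want["fwiou"], abs=1e-12)
        if want["dice"] is not None:
            assert dice_coefficient(c) == pytest.approx(want["dice"], abs=1e-12)

    def test_mpa_invariant_under_class_relabeling(self, rng):
        t, p = rng.random((7, 7)) > 0.5, rng.random((7, 7)) > 0.5
        a = mean_pixel_accuracy(accumulate_confusion(t, p))
        b = mean_pixel_accuracy(accumulate_confusion(~t, ~p))
        assert a == pytest.approx(b)

    def test_fwiou_between_min_and_max_class_iou(self, rng):
        t, p = rng.random((8, 8)) > 0.4, rng.random((8, 8)) > 0.6
        c = accumulate_confusion(t, p)
        ious = [v for v in ((c.p[i, i] / (c.p[i].sum() + c.p[:, i].sum() - c.p[i, i]))
                            for i in range(2))]
        assert min(ious) - 1e-12 <= fw_iou(c) <= max(ious) + 1e-12

    def test_dice_metric_complements_dice_loss(self, rng):
        t = (rng.random((10, 10)) > 0.5).astype(float)
        p = (rng.random((10, 10)) > 0.5).astype(float)
        c = accumulate_confusion(t, p)
        assert dice_coefficient(c) == pytest.approx(
            1 - dice_loss(t, p, epsilon=1e-12), abs=1e-9)

    def test_dice_at_least_iou(self, rng):
        for _ in range(20):
            t, p = rng.random((6, 6)) > 0.5, rng.random((6, 6)) > 0.5
            c = accumulate_confusion(t, p)
            fg_union = c.p[1].sum() + c.p[:, 1].sum() - c.p[1, 1]
            if fg_union == 0:
                continue
            assert dice_coefficient(c) >= c.p[1, 1] / fg_union - 1e-12


class TestHausdorff:
    def test_identical_masks_zero(self, rng):
        m = rng.random((10, 10)) > 0.6
        m[0, 0] = True
        assert hausdorff_distance(m, m) == 0.0

    def test_three_four_five_triangle(self):
        a = np.zeros((8, 8), bool)
        b = np.zeros((8, 8), bool)
        a[0, 0] = True
        b[3, 4] = True
        assert hausdorff_distance(a, b) == 5.0

    def test_asymmetric_directed_distances(self):
        a = np.zeros((12, 12), bool)
        b = np.zeros((12, 12), bool)
        a[0, 0] = a[10, 0] = True
        b[0, 0] = True
        assert hausdorff_distance(a, b) == 10.0

    def test_empty_mask_raises_not_zero(self):
        full = np.ones((4, 4), bool)
        with pytest.raises(EmptyMaskError):
            hausdorff_distance(full, np.zeros((4, 4), bool))

    @pytest.mark.parametrize("seed", range(15))
    def test_symmetry_and_brute_force_agreement(self, seed):
        r = np.random.default_rng(seed)
        a = r.random((12, 12)) > 0.7
        b = r.random((12, 12)) > 0.7
        if not a.any() or not b.any():
            return
        d1, d2 = hausdorff_distance(a, b), hausdorff_distance(b, a)
        assert d1 == d2
        assert d1 == pytest.approx(
            brute_force_hausdorff(boundary_pixels(a), boundary_pixels(b)), abs=1e-9)

    def test_boundary_extraction_drops_interior(self):
        m = np.zeros((7, 7), bool)
        m[1:6, 1:6] = True
        pts = {tuple(p) for p in boundary_pixels(m)}
        assert (3, 3) not in pts and (1, 1) in pts and len(pts) == 16

    def test_triangle_inequality_spot_check(self, rng):
        masks = []
        while len(masks) < 3:
            m = rng.random((10, 10)) > 0.7
            if m.any():
                masks.append(m)
        a, b, c = masks
        assert hausdorff_distance(a, c) <= (hausdorff_distance(a, b)
                                            + hausdorff_distance(b, c) + 1e-9)


class TestKappa:
    def test_identical_nonconstant_masks(self, rng):
        m = rng.random((9, 9)) > 0.5
        assert cohens_kappa(m, m) == pytest.approx(1.0)

    def test_constructed_po_08_pe_05(self):
        # 100 px, both raters 50% foreground, 80 agreements
        a = np.zeros(100, bool)
        a[:50] = True
        b = np.zeros(100, bool)
        b[:40] = True    # 40 TP
        b[50:60] = True  # 10 FP -> agreement = 40 + 40 = 80
        assert cohens_kappa(a.reshape(10, 10), b.reshape(10, 10)) == \
            pytest.approx(0.6)

    def test_complement_with_balanced_marginals(self):
        a = np.zeros((4, 4), bool)
        a[:2] = True
        assert cohens_kappa(a, ~a) == pytest.approx(-1.0)

    def test_label_swap_invariance(self, rng):
        a, b = rng.random((8, 8)) > 0.4, rng.random((8, 8)) > 0.6
        assert cohens_kappa(a, b) == pytest.approx(cohens_kappa(~a, ~b))

    def test_constant_identical_raters(self):
        z = np.zeros((5, 5), bool)
        assert cohens_kappa(z, z) == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_agreement_with_sklearn(self, seed):
        r = np.random.default_rng(seed)
        a = r.random(200) > 0.4
        b = r.random(200) > 0.55
        assert cohens_kappa(a.reshape(10, 20), b.reshape(10, 20)) == \
            pytest.approx(cohen_kappa_score(a, b), abs=1e-12)

    def test_hand_formula_agreement(self, rng):
        a, b = rng.random((12, 12)) > 0.5, rng.random((12, 12)) > 0.5
        assert cohens_kappa(a, b) == pytest.approx(kappa_by_hand(a, b), abs=1e-12)


class TestEvaluateDataset:
    def test_perfect_pair(self, rng):
        m = (rng.random((10, 10)) > 0.5).astype(np.uint8)
        m[0, 0] = 1
        rep = evaluate_dataset([(m, m)])
        assert rep.pa == rep.mpa == rep.miou == rep.fwiou == rep.dice == 1.0
        assert rep.hausdorff == 0.0 and rep.kappa == 1.0

    def test_duplication_idempotent_for_pooled_metrics(self, rng):
        t = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        p = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        one = evaluate_dataset([(t, p)])
        two = evaluate_dataset([(t, p), (t, p)])
        for k in ("pa", "mpa", "miou", "fwiou", "dice", "hausdorff", "kappa"):
            assert getattr(one, k) == pytest.approx(getattr(two, k))

    def test_pooled_pa_not_mean_of_per_image(self):
        t1 = np.ones((2, 2), np.uint8)
        p1 = np.ones((2, 2), np.uint8)          # 4/4 correct
        t2 = np.zeros((4, 4), np.uint8)
        t2[0] = 1
        p2 = np.zeros((4, 4), np.uint8)          # 12/16 correct
        rep = evaluate_dataset([(t1, p1), (t2, p2)])
        assert rep.pa == pytest.approx(16 / 20)  # pooled, not (1.0 + 0.75)/2

    def test_empty_prediction_reports_missing_hausdorff(self):
        t = np.zeros((6, 6), np.uint8)
        t[2:4, 2:4] = 1
        rep = evaluate_dataset([(t, np.zeros((6, 6), np.uint8))])
        assert rep.hausdorff is None
        assert rep.n_hausdorff_excluded == 1

    def test_report_json_roundtrip(self, tmp_path, rng):
        t = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        p = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        rep = evaluate_dataset([(t, p)])
        rep.to_json(tmp_path / "r.json")
        assert MetricReport.from_json(tmp_path / "r.json") == rep
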