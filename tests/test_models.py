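"""Losses vs brute-force oracles, matching, NMS, sampler, training contract."""

import math

import numpy as np
import pytest

from plaqueangle import geometry, models, phantom
from plaqueangle.labels import AngleBox
from plaqueangle.models import (
    AngleDetector,
    DenseUNet,
    DetectionTrainingRecord,
    DetModelConfig,
    SegModelConfig,
    TrainConfig,
    balanced_batch_sampler,
    detector_loss,
    match_anchors,
    nms_1d,
    weighted_bce_loss,
)


def bce_scalar(p, t, eps=1e-6):
    p = min(max(p, eps), 1 - eps)
    return -(t * math.log(p) + (1 - t) * math.log(1 - p))


class TestWeightedBCELoss:
    def test_perfect_prediction_is_near_zero(self):
        t = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert weighted_bce_loss(t, t, np.ones_like(t)) < 1e-4

    def test_single_pixel_hand_case(self):
        # predict 0.5, target 1, weight 2 -> 2 * (-ln 0.5) = 1.3863
        loss = weighted_bce_loss(np.array([[0.5]]), np.array([[1.0]]), np.array([[2.0]]))
        assert loss == pytest.approx(2 * math.log(2), abs=1e-4)
        assert loss == pytest.approx(1.3863, abs=1e-4)

    def test_uniform_weight_reduces_to_plain_bce(self, rng):
        p = rng.uniform(0.05, 0.95, size=(13, 17))
        t = (rng.random((13, 17)) > 0.5).astype(float)
        loss = weighted_bce_loss(p, t, np.ones_like(p))
        oracle = np.mean([bce_scalar(p[i, j], t[i, j]) for i in range(13) for j in range(17)])
        assert loss == pytest.approx(oracle, rel=1e-6)

    def test_matches_per_pixel_loop_oracle(self, rng):
        p = rng.uniform(0.01, 0.99, size=(9, 11))
        t = (rng.random((9, 11)) > 0.3).astype(float)
        w = rng.uniform(0.1, 5.0, size=(9, 11))
        loss = weighted_bce_loss(p, t, w, kernel_l2=0.125)
        acc = 0.0
        for i in range(9):
            for j in range(11):
                acc += w[i, j] * bce_scalar(p[i, j], t[i, j])
        assert loss == pytest.approx(acc / (9 * 11) + 0.125, rel=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            weighted_bce_loss(np.zeros((2, 2)), np.zeros((3, 3)), np.ones((2, 2)))


def make_record(rng, n_anchors=40, n_fg=8):
    fg = np.zeros(n_anchors, dtype=bool)
    fg[rng.choice(n_anchors, n_fg, replace=False)] = True
    valid = fg | (rng.random(n_anchors) > 0.3)
    return DetectionTrainingRecord(
        pred_obj=rng.uniform(0.01, 0.99, n_anchors),
        target_obj=fg.astype(float),
        valid_mask=valid,
        fg_mask=fg,
        pred_reg_bf=rng.normal(0, 0.2, (n_anchors, 2)),
        pred_cls=rng.uniform(0.01, 0.99, (n_anchors, 2)),
        target_cls=(rng.random((n_anchors, 2)) > 0.5).astype(float),
        pred_reg=rng.normal(0, 0.2, (n_anchors, 2)),
        target_reg=rng.normal(0, 0.2, (n_anchors, 2)),
    )


class TestDetectorLoss:
    def test_perfect_predictions_near_zero(self, rng):
        rec = make_record(rng)
        rec.pred_obj = np.clip(rec.target_obj, 1e-6, 1 - 1e-6)
        rec.pred_cls = np.clip(rec.target_cls, 1e-6, 1 - 1e-6)
        rec.pred_reg_bf = rec.target_reg.copy()
        rec.pred_reg = rec.target_reg.copy()
        total, comp = detector_loss(rec)
        assert total < 1e-4

    def test_ten_degree_offset_hand_case(self):
        """One matched anchor whose predicted interval is shifted by 10
        degrees: the normalized L1 angle term is 10/360 = 0.02778."""
        rec = DetectionTrainingRecord(
            pred_obj=np.array([1 - 1e-6]),
            target_obj=np.array([1.0]),
            valid_mask=np.array([True]),
            fg_mask=np.array([True]),
            pred_reg_bf=np.array([[10.0 / 360.0, 0.0]]) + np.array([[0.0, 0.0]]),
            pred_cls=np.array([[1 - 1e-6, 1e-6]]),
            target_cls=np.array([[1.0, 0.0]]),
            pred_reg=np.array([[10.0 / 360.0, 10.0 / 360.0]]),
            target_reg=np.zeros((1, 2)),
        )
        _, comp = detector_loss(rec)
        assert comp["loss_reg"] == pytest.approx(10.0 / 360.0, abs=1e-6)
        assert comp["loss_reg"] == pytest.approx(0.02778, abs=1e-4)

    def test_no_foreground_keeps_classification_only(self, rng):
        rec = make_record(rng, n_fg=0)
        total, comp = detector_loss(rec)
        assert comp["loss_reg_bf"] == 0.0
        assert comp["loss_reg"] == 0.0
        assert comp["loss_cls"] == 0.0
        assert comp["loss_cls_bf"] > 0.0
        assert total == pytest.approx(comp["loss_cls_bf"])

    def test_components_match_per_anchor_loop_oracle(self, rng):
        rec = make_record(rng)
        _, comp = detector_loss(rec)
        cls_bf = np.mean(
            [bce_scalar(rec.pred_obj[i], rec.target_obj[i]) for i in np.flatnonzero(rec.valid_mask)]
        )
        fg = np.flatnonzero(rec.fg_mask)
        reg_bf = np.mean([abs(rec.pred_reg_bf[i, k] - rec.target_reg[i, k]) for i in fg for k in (0, 1)])
        cls = np.mean([bce_scalar(rec.pred_cls[i, k], rec.target_cls[i, k]) for i in fg for k in (0, 1)])
        reg = np.mean([abs(rec.pred_reg[i, k] - rec.target_reg[i, k]) for i in fg for k in (0, 1)])
        assert comp["loss_cls_bf"] == pytest.approx(cls_bf, rel=1e-6)
        assert comp["loss_reg_bf"] == pytest.approx(reg_bf, rel=1e-6)
        assert comp["loss_cls"] == pytest.approx(cls, rel=1e-6)
        assert comp["loss_reg"] == pytest.approx(reg, rel=1e-6)


class TestMatchAnchors:
    def test_identical_interval_is_matched_with_iou_one(self):
        gt = [AngleBox("lipid", 100.0, 140.0)]
        m = match_anchors([(120.0, 40.0)], gt)
        assert m.fg_mask[0] and m.ious[0] == pytest.approx(1.0)

    def test_wrap_aware_iou_third(self):
        # anchor [350, 10) vs gt [0, 20): intersection 10, union 30
        gt = [AngleBox("lipid", 0.0, 20.0)]
        m = match_anchors([(0.0, 20.0)], gt)  # center 0 width 20 -> [350, 10)
        assert m.ious[0] == pytest.approx(1.0 / 3.0)

    def test_disjoint_is_background(self):
        gt = [AngleBox("lipid", 180.0, 200.0)]
        m = match_anchors([(10.0, 20.0), (190.0, 20.0)], gt)
        assert not m.valid_mask[0] or not m.fg_mask[0]
        assert m.ious[0] == 0.0

    def test_every_gt_claims_its_best_anchor(self):
        anchors = [((i + 0.5) * 8.0, 30.0) for i in range(45)]
        gt = [AngleBox("lipid", 33.0, 47.0), AngleBox("calcified", 200.0, 212.0)]
        m = match_anchors(anchors, gt)
        assert set(m.matched_gt[m.fg_mask]) == {0, 1}


def nms_oracle(boxes, thr):
    """Independent greedy suppression using 1-degree discretized IoU
    (exact for integer-degree boxes)."""
    grid = np.arange(360)

    def member(b):
        return ((grid - b.start_angle_deg) % 360) < b.width_deg

    order = sorted(boxes, key=lambda b: (-b.score, -b.width_deg, b.start_angle_deg % 360))
    kept = []
    for b in order:
        ok = True
        for k in kept:
            if k.plaque_class != b.plaque_class:
                continue
            inter = (member(b) & member(k)).sum()
            union = (member(b) | member(k)).sum()
            if union and inter / union > thr:
                ok = False
        if ok:
            kept.append(b)
    return kept


class TestNMS:
    def test_single_box_survives(self):
        b = AngleBox("lipid", 10.0, 40.0, 0.7)
        assert nms_1d([b], 0.3) == [b]

    def test_duplicate_keeps_higher_score(self):
        hi = AngleBox("lipid", 10.0, 40.0, 0.9)
        lo = AngleBox("lipid", 10.0, 40.0, 0.8)
        assert nms_1d([lo, hi], 0.3) == [hi]

    def test_different_classes_do_not_suppress(self):
        a = AngleBox("lipid", 10.0, 40.0, 0.9)
        b = AngleBox("calcified", 10.0, 40.0, 0.8)
        assert set(nms_1d([a, b], 0.3)) == {a, b}

    def test_matches_exhaustive_oracle_on_random_sets(self, rng):
        for _ in range(50):
            boxes = []
            for _ in range(int(rng.integers(2, 12))):
                s = float(rng.integers(0, 360))
                w = float(rng.integers(5, 180))
                boxes.append(
                    AngleBox(
                        "lipid" if rng.random() < 0.5 else "calcified",
                        s,
                        (s + w) % 360.0,
                        round(float(rng.uniform(0.05, 0.95)), 3),
                    )
                )
            assert nms_1d(boxes, 0.3) == nms_oracle(boxes, 0.3)


class TestBalancedSampler:
    def test_single_class_ratio(self):
        classes = ["lipid"] * 5 + ["normal"] * 5
        batches = list(
            balanced_batch_sampler(classes, ratio=(1, 0, 0, 0), batch_size=8, seed=0, n_batches=10)
        )
        for b in batches:
            assert all(classes[i] == "lipid" for i in b)

    def test_fixed_seed_reproduces_stream(self):
        classes = ["lipid", "calcified", "mixed", "normal"] * 10
        a = [b.tolist() for b in balanced_batch_sampler(classes, seed=5, n_batches=20)]
        b = [b.tolist() for b in balanced_batch_sampler(classes, seed=5, n_batches=20)]
        assert a == b

    def test_missing_class_renormalizes_with_warning(self):
        classes = ["lipid"] * 4 + ["normal"] * 4
        with pytest.warns(UserWarning, match="renormaliz"):
            batches = list(balanced_batch_sampler(classes, batch_size=16, seed=0, n_batches=5))
        drawn = {classes[i] for b in batches for i in b}
        assert drawn <= {"lipid", "normal"}

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            next(balanced_batch_sampler([], n_batches=1))


@pytest.fixture(scope="module")
def tiny_phantom():
    cfg = phantom.PhantomConfig(
        n_frames=12,
        image_size=64,
        pixel_spacing_mm=0.18,
        noise_sd_hu=10.0,
        lesion_specs=(
            phantom.LesionSpec((2, 10), [("calcified", 60.0, 150.0, 0.9), ("lipid", 200.0, 280.0, 0.9)], 0.6),
        ),
        seed=5,
    )
    return phantom.generate_stack(cfg)


TINY_SEG = SegModelConfig(image_size=64, base_channels=2, growth_rate=2, dense_block_layers=1)


class TestSegmenterTraining:
    def test_loss_decreases_and_is_reproducible(self, tiny_phantom):
        stack, gt, _ = tiny_phantom
        tc = TrainConfig(epochs=3, batch_size=4, learning_rate=1e-3, seed=0)
        _, curve1 = models.train_segmenter(stack, gt, TINY_SEG, tc, augment=False)
        _, curve2 = models.train_segmenter(stack, gt, TINY_SEG, tc, augment=False)
        assert curve1[-1] < curve1[0]
        np.testing.assert_allclose(curve1, curve2, rtol=1e-5)

    def test_l2_penalty_shrinks_kernels(self, tiny_phantom):
        stack, gt, _ = tiny_phantom
        tc = TrainConfig(epochs=2, batch_size=4, learning_rate=1e-3, seed=0)
        m0, _ = models.train_segmenter(
            stack, gt, SegModelConfig(**{**TINY_SEG.__dict__, "l2_lambda": 0.0}), tc, augment=False
        )
        m1, _ = models.train_segmenter(
            stack, gt, SegModelConfig(**{**TINY_SEG.__dict__, "l2_lambda": 0.05}), tc, augment=False
        )
        assert m1.kernel_sq_norm().item() < m0.kernel_sq_norm().item()

    def test_dropout_only_in_training_mode(self, tiny_phantom):
        stack, _, _ = tiny_phantom
        model = DenseUNet(TINY_SEG, seed=0)
        x = geometry.build_block(stack, 5, "cartesian", block_size=64).values.transpose(2, 0, 1)[None]
        e1 = model.forward(x, training=False).data
        e2 = model.forward(x, training=False).data
        np.testing.assert_array_equal(e1, e2)
        rng = np.random.default_rng(0)
        t1 = model.forward(x, training=True, rng=rng).data
        t2 = model.forward(x, training=True, rng=rng).data
        assert not np.array_equal(t1, t2)

    def test_prediction_shape_and_range(self, tiny_phantom):
        stack, _, _ = tiny_phantom
        model = DenseUNet(TINY_SEG, seed=0)
        block = geometry.build_block(stack, 5, "cartesian", block_size=64)
        pred = models.predict_segmenter(model, block)
        assert set(pred.maps) == {"lipid", "calcified"}
        for m in pred.maps.values():
            assert m.shape == (64, 64)
            assert (m >= 0).all() and (m <= 1).all()

    def test_save_load_round_trip(self, tiny_phantom, tmp_path):
        stack, _, _ = tiny_phantom
        model = DenseUNet(TINY_SEG, seed=3)
        model.save(tmp_path / "seg")
        loaded = DenseUNet.load(tmp_path / "seg")
        block = geometry.build_block(stack, 4, "cartesian", block_size=64)
        p1 = models.predict_segmenter(model, block)
        p2 = models.predict_segmenter(loaded, block)
        np.testing.assert_array_equal(p1.maps["lipid"], p2.maps["lipid"])


class TestDetector:
    def test_no_mask_head_exists(self):
        model = AngleDetector(DetModelConfig(), seed=0)
        assert model.heads == ("classification", "angle_regression")
        assert not any("mask" in attr for attr in vars(model))

    def test_anchors_tile_angle_axis_only(self):
        model = AngleDetector(DetModelConfig(), seed=0)
        anchors = model.anchors
        assert len(anchors) == 45 * 5
        # anchors are (center, width) pairs on the angle axis: no radial
        # coordinate exists, every proposal spans the full radial extent
        assert all(len(a) == 2 for a in anchors)
        centers = sorted({c for c, _ in anchors})
        assert centers[0] == pytest.approx(4.0)
        assert len(centers) == 45

    def test_predicted_boxes_respect_score_threshold(self, tiny_phantom):
        stack, _, _ = tiny_phantom
        model = AngleDetector(DetModelConfig(), seed=0)
        block = geometry.build_block(stack, 5, "polar")
        thresholds = {"lipid": 0.3, "calcified": 0.5}
        boxes = models.predict_detector(model, block, score_thresholds=thresholds)
        for b in boxes:
            assert b.score >= thresholds[b.plaque_class]

    def test_training_loss_decreases(self, tiny_phantom):
        stack, gt, _ = tiny_phantom
        tc = TrainConfig(epochs=4, batch_size=4, learning_rate=1e-3, seed=0)
        _, curve = models.train_detector(stack, gt, DetModelConfig(base_channels=4), tc)
        assert curve[-1] < curve[0]

    def test_save_load_round_trip(self, tiny_phantom, tmp_path):
        stack, _, _ = tiny_phantom
        model = AngleDetector(DetModelConfig(base_channels=2), seed=1)
        model.save(tmp_path / "det")
        loaded = AngleDetector.load(tmp_path / "det")
        block = geometry.build_block(stack, 6, "polar")
        out1 = model.forward(block.values.transpose(2, 0, 1)[None])
        out2 = loaded.forward(block.values.transpose(2, 0, 1)[None])
        np.testing.assert_array_equal(out1["obj"].data, out2["obj"].data)
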