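"""Two-stage detector: box arithmetic, NMS, RoIAlign semantics,
training smoke/determinism, inference contracts, ablation structure."""

import numpy as np
import pytest

from chickseg import nn
from chickseg import synthetic as S
from chickseg.backbone import BackboneConfig
from chickseg.detector import (DetectorConfig, MaskRCNN, ModelConfig,
                               TrainConfig, decode_boxes, encode_boxes,
                               detections_to_coco_results, nms, paste_mask,
                               predict, roi_align, rpn_propose, train)
from chickseg.neck import CEMConfig, NeckConfig


def tiny_model_config():
    """Smallest full-architecture config, for fast unit tests."""
    return ModelConfig(
        backbone=BackboneConfig(depth=50, width_mult=0.0625),
        neck=NeckConfig(out_channels=16, latent_channels=8,
                        cem=CEMConfig(dilations=(1, 2))),
        detector=DetectorConfig(rpn_channels=16, head_dim=64,
                                mask_channels=16, rpn_pre_nms_topk=200,
                                rpn_post_nms_topk=50, roi_batch=16,
                                roi_pos_frac=0.5, train_gt_jitter=4),
    )


class TestBoxArithmetic:
    def test_zero_deltas_decode_identity(self, rng):
        anchors = rng.uniform(10, 100, (6, 2))
        anchors = np.concatenate([anchors, anchors + 20], axis=1)
        decoded = decode_boxes(anchors, np.zeros((6, 4), np.float32))
        assert np.allclose(decoded, anchors, atol=1e-5)

    def test_encode_decode_round_trip(self, rng):
        anchors = np.array([[10, 10, 50, 40], [0, 0, 30, 60]], float)
        gt = np.array([[12, 8, 55, 44], [5, 3, 28, 70]], float)
        deltas = encode_boxes(anchors, gt)
        back = decode_boxes(anchors, deltas)
        assert np.allclose(back, gt, atol=1e-4)

    def test_nms_suppresses_overlaps_deterministically(self):
        boxes = np.array([[0, 0, 10, 10], [1, 1, 11, 11], [50, 50, 60, 60]],
                         float)
        scores = np.array([0.9, 0.8, 0.7])
        keep = nms(boxes, scores, 0.5)
        assert keep.tolist() == [0, 2]
        # equal scores break ties by index
        keep2 = nms(boxes, np.array([0.5, 0.5, 0.5]), 0.5)
        assert keep2.tolist() == [0, 2]


class TestRoiAlign:
    def test_constant_map_gives_constant_patch(self):
        feat = np.full((2, 16, 16), 3.5, np.float32)
        patch = roi_align(feat, [2.3, 4.1, 11.7, 13.2], 7)
        assert patch.shape == (2, 7, 7)
        assert np.allclose(patch, 3.5, atol=1e-5)

    def test_grid_aligned_box_on_ramp(self):
        """On a linear ramp, bin averages equal the ramp at bin centres
        (closed-form bilinear evaluation)."""
        xs = np.arange(16, dtype=np.float32)
        feat = np.broadcast_to(xs, (1, 16, 16)).copy()
        patch = roi_align(feat, [4.0, 4.0, 12.0, 12.0], 4)
        # bin width 2: centres at x = 4 + (i + 0.5) * 2 - 0.5 (pixel centre)
        expected = 4 + (np.arange(4) + 0.5) * 2 - 0.5
        assert np.allclose(patch[0, 0], expected, atol=1e-4)

    def test_subcell_box_size_contract(self):
        feat = np.random.default_rng(0).normal(size=(3, 8, 8)) \
            .astype(np.float32)
        patch = roi_align(feat, [2.1, 2.1, 2.4, 2.6], 7)
        assert patch.shape == (3, 7, 7)
        assert np.isfinite(patch).all()

    def test_degenerate_box_rejected(self):
        feat = np.zeros((1, 8, 8), np.float32)
        with pytest.raises(ValueError):
            roi_align(feat, [5.0, 5.0, 5.0, 9.0], 7)


class TestMaskPaste:
    def test_saturated_probabilities(self):
        full = paste_mask(np.ones((28, 28)), np.array([4, 4, 20, 20]),
                          32, 32)
        empty = paste_mask(np.zeros((28, 28)), np.array([4, 4, 20, 20]),
                           32, 32)
        assert full[5:19, 5:19].all()
        assert not full[:3].any()
        assert not empty.any()


class TestProposals:
    def test_boxes_clipped_to_image(self):
        model = MaskRCNN(tiny_model_config(), seed=0)
        img = np.random.default_rng(1).normal(
            size=(3, 64, 64)).astype(np.float32)
        boxes, scores = rpn_propose(model, img)
        assert (boxes[:, 0] >= 0).all() and (boxes[:, 1] >= 0).all()
        assert (boxes[:, 2] <= 64).all() and (boxes[:, 3] <= 64).all()
        assert (boxes[:, 2] > boxes[:, 0]).all()
        assert (boxes[:, 3] > boxes[:, 1]).all()

    def test_proposals_deterministic(self):
        model = MaskRCNN(tiny_model_config(), seed=0)
        img = np.random.default_rng(2).normal(
            size=(3, 64, 64)).astype(np.float32)
        b1, s1 = rpn_propose(model, img)
        b2, s2 = rpn_propose(model, img)
        assert np.array_equal(b1, b2) and np.array_equal(s1, s2)


class TestTraining:
    def test_first_epoch_loss_finite(self):
        ds, pix, _ = S.make_easy_dataset(4, seed=3, size=128)
        tc = TrainConfig(batch_size=2, base_lr=0.002, epochs=1,
                         input_size=128, seed=0, warmup_steps=5)
        _, log = train(ds, pix, tiny_model_config(), tc)
        assert len(log) == 1 and np.isfinite(log[0]["loss"])

    def test_seed_reproducible_loss_trajectory(self):
        ds, pix, _ = S.make_easy_dataset(4, seed=3, size=128)
        tc = TrainConfig(batch_size=2, base_lr=0.002, epochs=2,
                         input_size=128, seed=7, warmup_steps=5)
        _, log1 = train(ds, pix, tiny_model_config(), tc)
        _, log2 = train(ds, pix, tiny_model_config(), tc)
        assert [r["loss"] for r in log1] == [r["loss"] for r in log2]

    def test_loss_decreases_over_micro_run(self):
        ds, pix, _ = S.make_easy_dataset(6, seed=4, size=128)
        tc = TrainConfig(batch_size=2, base_lr=0.004, epochs=20,
                         input_size=128, seed=0, max_steps=60,
                         warmup_steps=10, lr_decay_epochs=())
        _, log = train(ds, pix, tiny_model_config(), tc)
        assert log[-1]["loss"] < log[0]["loss"]

    def test_empty_split_rejected(self):
        from chickseg.dataset import CocoDataset
        with pytest.raises(ValueError):
            train(CocoDataset(), {}, tiny_model_config(), TrainConfig())


class TestInference:
    def test_untrained_model_blank_image_empty(self):
        model = MaskRCNN(tiny_model_config(), seed=0)
        blank = np.full((64, 64), 90, np.uint8)
        res = predict({1: blank}, model, score_thresh=0.5)
        assert res[1] == []

    def test_inference_deterministic(self):
        model = MaskRCNN(tiny_model_config(), seed=1)
        img = np.random.default_rng(5).integers(
            0, 255, (64, 64), dtype=np.uint8)
        r1 = predict({1: img}, model, score_thresh=0.01)
        r2 = predict({1: img}, model, score_thresh=0.01)
        assert len(r1[1]) == len(r2[1])
        for a, b in zip(r1[1], r2[1]):
            assert a["score"] == b["score"] and a["bbox"] == b["bbox"]

    def test_coco_results_schema(self):
        model = MaskRCNN(tiny_model_config(), seed=2)
        img = np.random.default_rng(6).integers(
            0, 255, (64, 64), dtype=np.uint8)
        res = predict({3: img}, model, score_thresh=0.0)
        payload = detections_to_coco_results(res)
        for rec in payload:
            assert set(rec) == {"image_id", "category_id", "bbox",
                                "score", "segmentation"}
            assert rec["image_id"] == 3
            assert rec["segmentation"]["size"] == [64, 64]


class TestAblationStructure:
    def variants(self):
        base = tiny_model_config()
        out = {}
        for cbam in (False, True):
            for neck_type in ("fpn", "acfpn"):
                cfg = ModelConfig(
                    backbone=BackboneConfig(
                        depth=base.backbone.depth,
                        width_mult=base.backbone.width_mult,
                        cbam_enabled=cbam),
                    neck=NeckConfig(type=neck_type, out_channels=16,
                                    latent_channels=8,
                                    cem=CEMConfig(dilations=(1, 2))),
                    detector=base.detector)
                out[(cbam, neck_type)] = cfg
        return out

    def test_parameter_counts_strictly_increase(self):
        counts = {k: MaskRCNN(cfg, seed=0).num_parameters()
                  for k, cfg in self.variants().items()}
        plain = counts[(False, "fpn")]
        full = counts[(True, "acfpn")]
        assert plain < counts[(True, "fpn")] < full
        assert plain < counts[(False, "acfpn")] < full

    def test_all_variants_run_forward(self):
        img = np.random.default_rng(7).integers(
            0, 255, (64, 64), dtype=np.uint8)
        for cfg in self.variants().values():
            model = MaskRCNN(cfg, seed=0)
            res = predict({1: img}, model, score_thresh=0.99)
            assert 1 in res
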