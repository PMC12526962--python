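"""Two-stage detector: RPN over the pyramid, RoIAlign, box/class/mask heads.

The assembly follows the classic detect-then-segment design: anchors on
P2-P6 are scored and regressed by a shared RPN head; proposals are
merged across levels, deduplicated by NMS and fed through RoIAlign to a
two-layer box head (classification over the four aggregation states plus
background, class-specific box regression) and a small convolutional
mask head predicting 28x28 logits per class.  All sampling ratios, NMS
thresholds and proposal counts live in DetectorConfig.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import time

import numpy as np
from PIL import Image

from . import nn
from .backbone import BackboneConfig, ResNetBackbone
from .dataset import CocoDataset, rasterize_polygons
from .evaluation import rle_encode
from .neck import NeckConfig, Pyramid
from .nn import Tensor

BBOX_CLIP = float(np.log(1000.0 / 16.0))


@dataclasses.dataclass
class DetectorConfig:
    num_classes: int = 4
    anchor_scales: tuple[float, ...] = (32, 64, 128, 256, 512)
    anchor_ratios: tuple[float, ...] = (0.5, 1.0, 2.0)
    strides: tuple[int, ...] = (4, 8, 16, 32, 64)
    rpn_channels: int = 256
    rpn_pre_nms_topk: int = 1000
    rpn_post_nms_topk: int = 300
    rpn_nms_thresh: float = 0.7
    rpn_fg_iou: float = 0.7
    rpn_bg_iou: float = 0.3
    rpn_batch: int = 256
    rpn_pos_frac: float = 0.5
    roi_fg_iou: float = 0.5
    roi_batch: int = 128
    roi_pos_frac: float = 0.25
    # during training, append this many jittered copies of every truth box
    # to the proposal set: gives the box head real regression targets and
    # keeps positives present even while the RPN is still warming up
    train_gt_jitter: int = 4
    train_gt_jitter_frac: float = 0.25
    head_dim: int = 1024
    mask_channels: int = 256
    mask_size: int = 28
    score_thresh: float = 0.5
    nms_thresh: float = 0.5
    max_detections: int = 100
    min_box_size: float = 2.0


@dataclasses.dataclass
class ModelConfig:
    backbone: BackboneConfig = dataclasses.field(default_factory=BackboneConfig)
    neck: NeckConfig = dataclasses.field(default_factory=NeckConfig)
    detector: DetectorConfig = dataclasses.field(default_factory=DetectorConfig)


@dataclasses.dataclass
class TrainConfig:
    batch_size: int = 4
    base_lr: float = 0.004
    epochs: int = 70
    input_size: int = 512
    seed: int = 0
    momentum: float = 0.9
    weight_decay: float = 1e-4
    lr_decay_epochs: tuple[int, ...] = (50, 65)
    lr_decay_factor: float = 0.1
    warmup_steps: int = 50              # linear LR ramp from 10%
    max_grad_norm: float = 10.0         # global gradient-norm clip
    max_steps: int | None = None        # cap total steps (micro runs)

    def __post_init__(self):
        if min(self.batch_size, self.epochs, self.input_size) <= 0 \
                or self.base_lr <= 0:
            raise ValueError("train config values must be positive")


# -- box utilities (xyxy) -------------------------------------------------

def box_area(b: np.ndarray) -> np.ndarray:
    return np.maximum(b[:, 2] - b[:, 0], 0) * np.maximum(b[:, 3] - b[:, 1], 0)


def box_iou_xyxy(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.asarray(a, np.float64).reshape(-1, 4)
    b = np.asarray(b, np.float64).reshape(-1, 4)
    ix = np.maximum(0.0, np.minimum(a[:, None, 2], b[None, :, 2])
                    - np.maximum(a[:, None, 0], b[None, :, 0]))
    iy = np.maximum(0.0, np.minimum(a[:, None, 3], b[None, :, 3])
                    - np.maximum(a[:, None, 1], b[None, :, 1]))
    inter = ix * iy
    union = box_area(a)[:, None] + box_area(b)[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(union > 0, inter / union, 0.0)


def encode_boxes(anchors: np.ndarray, gt: np.ndarray) -> np.ndarray:
    """(dx, dy, dw, dh) regression targets mapping anchors onto gt."""
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + 0.5 * aw
    ay = anchors[:, 1] + 0.5 * ah
    gw = gt[:, 2] - gt[:, 0]
    gh = gt[:, 3] - gt[:, 1]
    gx = gt[:, 0] + 0.5 * gw
    gy = gt[:, 1] + 0.5 * gh
    return np.stack([(gx - ax) / aw, (gy - ay) / ah,
                     np.log(gw / aw), np.log(gh / ah)], axis=1
                    ).astype(np.float32)


def decode_boxes(anchors: np.ndarray, deltas: np.ndarray) -> np.ndarray:
    aw = anchors[:, 2] - anchors[:, 0]
    ah = anchors[:, 3] - anchors[:, 1]
    ax = anchors[:, 0] + 0.5 * aw
    ay = anchors[:, 1] + 0.5 * ah
    dx, dy = deltas[:, 0], deltas[:, 1]
    dw = np.clip(deltas[:, 2], -BBOX_CLIP, BBOX_CLIP)
    dh = np.clip(deltas[:, 3], -BBOX_CLIP, BBOX_CLIP)
    cx = ax + dx * aw
    cy = ay + dy * ah
    w = aw * np.exp(dw)
    h = ah * np.exp(dh)
    return np.stack([cx - 0.5 * w, cy - 0.5 * h,
                     cx + 0.5 * w, cy + 0.5 * h], axis=1)


def clip_boxes(boxes: np.ndarray, height: int, width: int) -> np.ndarray:
    out = boxes.copy()
    out[:, 0::2] = np.clip(out[:, 0::2], 0, width)
    out[:, 1::2] = np.clip(out[:, 1::2], 0, height)
    return out


def nms(boxes: np.ndarray, scores: np.ndarray, thresh: float) -> np.ndarray:
    """Greedy NMS; returns kept indices in descending-score order with
    index as the deterministic tie-break."""
    order = np.argsort(-scores, kind="mergesort")
    keep = []
    suppressed = np.zeros(len(boxes), dtype=bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(i)
        if len(boxes) > 1:
            ious = box_iou_xyxy(boxes[i:i + 1], boxes).ravel()
            suppressed |= ious > thresh
            suppressed[i] = True
    return np.array(keep, dtype=np.int64)


def generate_anchors(h: int, w: int, stride: int, scale: float,
                     ratios) -> np.ndarray:
    ys = (np.arange(h) + 0.5) * stride
    xs = (np.arange(w) + 0.5) * stride
    cy, cx = np.meshgrid(ys, xs, indexing="ij")
    anchors = []
    for r in ratios:
        bh = scale * np.sqrt(r)
        bw = scale / np.sqrt(r)
        anchors.append(np.stack([cx - bw / 2, cy - bh / 2,
                                 cx + bw / 2, cy + bh / 2], axis=-1))
    # (H, W, A, 4) -> (H*W*A, 4); A varies fastest within a cell
    return np.stack(anchors, axis=2).reshape(-1, 4).astype(np.float32)


# -- model ----------------------------------------------------------------

class RPNHead(nn.Module):
    def __init__(self, channels: int, num_anchors: int,
                 rng: np.random.Generator):
        self.conv = nn.Conv2d(channels, channels, 3, rng, padding=1)
        self.cls = nn.Conv2d(channels, num_anchors, 1, rng)
        self.reg = nn.Conv2d(channels, num_anchors * 4, 1, rng)
        # near-zero prediction heads: early objectness is uniform, so the
        # first proposals are well-spread anchors rather than noise
        self.cls.weight.data *= 0.01
        self.reg.weight.data *= 0.01

    def forward(self, feat: Tensor):
        h = nn.relu(self.conv(feat))
        return self.cls(h), self.reg(h)


class BoxHead(nn.Module):
    def __init__(self, in_dim: int, cfg: DetectorConfig,
                 rng: np.random.Generator):
        k = cfg.num_classes + 1
        self.fc1 = nn.Linear(in_dim, cfg.head_dim, rng)
        self.fc2 = nn.Linear(cfg.head_dim, cfg.head_dim, rng)
        self.cls = nn.Linear(cfg.head_dim, k, rng)
        self.reg = nn.Linear(cfg.head_dim, 4 * k, rng)
        # detection heads start near zero so early decodes stay tame
        self.cls.weight.data *= 0.01
        self.reg.weight.data *= 0.01

    def forward(self, patches: Tensor):
        n = patches.shape[0]
        flat = nn.reshape(patches, (n, -1))
        h = nn.relu(self.fc2(nn.relu(self.fc1(flat))))
        return self.cls(h), self.reg(h)


class MaskHead(nn.Module):
    def __init__(self, in_channels: int, cfg: DetectorConfig,
                 rng: np.random.Generator):
        c = cfg.mask_channels
        self.conv1 = nn.ConvNormRelu(in_channels, c, 3, rng, padding=1)
        self.conv2 = nn.ConvNormRelu(c, c, 3, rng, padding=1)
        self.out = nn.Conv2d(c, cfg.num_classes, 1, rng)

    def forward(self, patches: Tensor) -> Tensor:
        h = self.conv2(self.conv1(patches))
        return self.out(nn.upsample_nearest2x(h))      # 14 -> 28


class MaskRCNN(nn.Module):
    """Backbone + neck + RPN + RoI heads, configurable ablations."""

    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0):
        self.cfg = cfg = cfg or ModelConfig()
        rng = np.random.default_rng(seed)
        self.backbone = ResNetBackbone(cfg.backbone, rng)
        self.neck = Pyramid(self.backbone.out_channels, cfg.neck, rng)
        det = cfg.detector
        oc = cfg.neck.out_channels
        self.rpn = RPNHead(oc, len(det.anchor_ratios), rng)
        self.box_head = BoxHead(oc * 7 * 7, det, rng)
        self.mask_head = MaskHead(oc, det, rng)
        self.level_names = ["P2", "P3", "P4", "P5", "P6"]

    # ---- shared forward pieces
    def extract_pyramid(self, image: Tensor) -> dict[str, Tensor]:
        return self.neck(self.backbone(image))

    def rpn_forward(self, pyramid: dict[str, Tensor], img_hw: tuple[int, int]):
        """Per-level objectness/deltas plus matching anchors."""
        det = self.cfg.detector
        logits, deltas, anchors = [], [], []
        for name, stride, scale in zip(self.level_names, det.strides,
                                       det.anchor_scales):
            feat = pyramid[name]
            cls, reg = self.rpn(feat)
            a = len(det.anchor_ratios)
            h, w = cls.shape[2], cls.shape[3]
            # (1,A,H,W) -> (H*W*A,) matching anchor layout
            logits.append(nn.reshape(nn.transpose(cls, (0, 2, 3, 1)), (-1,)))
            deltas.append(nn.reshape(nn.transpose(reg, (0, 2, 3, 1)),
                                     (-1, 4)))
            anchors.append(generate_anchors(h, w, stride, scale,
                                            det.anchor_ratios))
        return logits, deltas, anchors

    def propose(self, logits, deltas, anchors, img_hw, training: bool):
        """Merge levels, decode, clip, NMS, keep top-N proposals."""
        det = self.cfg.detector
        H, W = img_hw
        all_boxes, all_scores = [], []
        for lg, dl, an in zip(logits, deltas, anchors):
            scores = lg.data
            k = min(det.rpn_pre_nms_topk, len(scores))
            idx = np.argsort(-scores, kind="mergesort")[:k]
            boxes = decode_boxes(an[idx], dl.data[idx])
            all_boxes.append(boxes)
            all_scores.append(scores[idx])
        boxes = clip_boxes(np.concatenate(all_boxes), H, W)
        scores = np.concatenate(all_scores)
        wh_ok = ((boxes[:, 2] - boxes[:, 0]) >= det.min_box_size) \
            & ((boxes[:, 3] - boxes[:, 1]) >= det.min_box_size)
        boxes, scores = boxes[wh_ok], scores[wh_ok]
        if len(boxes) == 0:
            return np.zeros((0, 4), np.float32), np.zeros(0, np.float32)
        keep = nms(boxes, scores, det.rpn_nms_thresh)[:det.rpn_post_nms_topk]
        return boxes[keep].astype(np.float32), scores[keep]

    def roi_features(self, pyramid, boxes: np.ndarray, out_size: int
                     ) -> Tensor:
        """Level-assigned RoIAlign over P2-P5."""
        det = self.cfg.detector
        if len(boxes) == 0:
            oc = self.cfg.neck.out_channels
            return Tensor(np.zeros((0, oc, out_size, out_size), np.float32))
        wh = np.sqrt(np.maximum(box_area(boxes), 1e-6))
        levels = np.clip(np.floor(4 + np.log2(wh / 224.0)), 2, 5).astype(int)
        pieces, order = [], []
        for lv in (2, 3, 4, 5):
            sel = np.flatnonzero(levels == lv)
            if len(sel) == 0:
                continue
            feat = pyramid[f"P{lv}"]
            fm = nn.reshape(feat, feat.shape[1:])
            patch = nn.roi_align(fm, boxes[sel], out_size,
                                 1.0 / det.strides[lv - 2])
            pieces.append(patch)
            order.append(sel)
        out = pieces[0] if len(pieces) == 1 else nn.concat(pieces, axis=0)
        perm = np.concatenate(order)
        inv = np.argsort(perm, kind="mergesort")
        # reorder rows back to the input box order
        return _take_rows(out, inv)


def _take_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    from .nn.tensor import _node
    data = t.data[idx]

    def bw(g):
        full = np.zeros_like(t.data)
        np.add.at(full, idx, g)
        t._accumulate(full)

    return _node(data, (t,), bw)


# -- functional pieces used by tests and the pipeline ---------------------

def rpn_propose(model: MaskRCNN, image: np.ndarray) -> tuple[np.ndarray,
                                                             np.ndarray]:
    """Proposal boxes (xyxy) and objectness scores for one (3,H,W) image."""
    with nn.no_grad():
        pyr = model.extract_pyramid(Tensor(np.asarray(image,
                                                      np.float32)[None]))
        logits, deltas, anchors = model.rpn_forward(
            pyr, image.shape[1:])
        return model.propose(logits, deltas, anchors, image.shape[1:],
                             training=False)


def roi_align(level_map: np.ndarray, box: np.ndarray, output_size: int,
              spatial_scale: float = 1.0) -> np.ndarray:
    """Single-box RoIAlign on a (C,H,W) array (bilinear, no quantisation)."""
    box = np.asarray(box, np.float64).reshape(-1, 4)
    with nn.no_grad():
        out = nn.roi_align(Tensor(np.asarray(level_map, np.float32)),
                           box, output_size, spatial_scale)
    return out.data[0] if box.shape[0] == 1 else out.data


# -- training -------------------------------------------------------------

def _sample(pos: np.ndarray, neg: np.ndarray, batch: int, pos_frac: float,
            rng: np.random.Generator):
    n_pos = min(len(pos), int(batch * pos_frac))
    n_neg = min(len(neg), batch - n_pos)
    pos = rng.permutation(pos)[:n_pos]
    neg = rng.permutation(neg)[:n_neg]
    return pos, neg


def _mask_target(gt_mask: np.ndarray, box: np.ndarray, size: int
                 ) -> np.ndarray:
    x1, y1, x2, y2 = box
    h, w = gt_mask.shape
    x1i, y1i = int(np.floor(x1)), int(np.floor(y1))
    x2i, y2i = int(np.ceil(x2)), int(np.ceil(y2))
    crop = gt_mask[max(y1i, 0):max(y2i, y1i + 1),
                   max(x1i, 0):max(x2i, x1i + 1)]
    if crop.size == 0:
        return np.zeros((size, size), np.float32)
    img = Image.fromarray(crop.astype(np.uint8) * 255)
    img = img.resize((size, size), Image.BILINEAR)
    return (np.asarray(img) > 127).astype(np.float32)


@dataclasses.dataclass
class GroundTruth:
    boxes: np.ndarray           # (G,4) xyxy
    labels: np.ndarray          # (G,) in 1..K
    masks: list[np.ndarray]     # boolean HxW


def ground_truth_from_coco(ds: CocoDataset) -> dict[int, GroundTruth]:
    meta = {im["id"]: im for im in ds.images}
    per_img: dict[int, list] = {im["id"]: [] for im in ds.images}
    for a in ds.annotations:
        per_img[a["image_id"]].append(a)
    out = {}
    for img_id, anns in per_img.items():
        im = meta[img_id]
        boxes, labels, masks = [], [], []
        for a in anns:
            x, y, w, h = a["bbox"]
            boxes.append([x, y, x + w, y + h])
            labels.append(a["category_id"])
            masks.append(rasterize_polygons(
                [np.asarray(p).reshape(-1, 2) for p in a["segmentation"]],
                im["height"], im["width"]))
        out[img_id] = GroundTruth(
            np.asarray(boxes, np.float32).reshape(-1, 4),
            np.asarray(labels, np.int64), masks)
    return out


def prepare_image(pixels: np.ndarray) -> np.ndarray:
    """uint8 grayscale or RGB image -> normalised (3,H,W) float32."""
    arr = np.asarray(pixels, np.float32) / 255.0 - 0.5
    if arr.ndim == 2:
        arr = np.stack([arr] * 3)
    else:
        arr = arr.transpose(2, 0, 1)
    return arr.astype(np.float32)


def compute_losses(model: MaskRCNN, image: np.ndarray, gt: GroundTruth,
                   rng: np.random.Generator) -> dict[str, Tensor]:
    det = model.cfg.detector
    H, W = image.shape[1:]
    pyramid = model.extract_pyramid(Tensor(image[None]))
    logits, deltas, anchors = model.rpn_forward(pyramid, (H, W))
    cat_logits = nn.concat(logits, axis=0)
    cat_deltas = nn.concat(deltas, axis=0)
    all_anchors = np.concatenate(anchors)

    losses: dict[str, Tensor] = {}
    # ---- RPN targets
    if len(gt.boxes):
        ious = box_iou_xyxy(all_anchors, gt.boxes)
        best_gt = ious.argmax(axis=1)
        best_iou = ious[np.arange(len(all_anchors)), best_gt]
        labels = -np.ones(len(all_anchors), np.int64)
        labels[best_iou < det.rpn_bg_iou] = 0
        labels[best_iou >= det.rpn_fg_iou] = 1
        # every truth keeps its best anchor
        labels[ious.argmax(axis=0)] = 1
        pos, neg = _sample(np.flatnonzero(labels == 1),
                           np.flatnonzero(labels == 0),
                           det.rpn_batch, det.rpn_pos_frac, rng)
        sel = np.concatenate([pos, neg])
        tgt = np.zeros(len(sel), np.float32)
        tgt[:len(pos)] = 1.0
        losses["rpn_cls"] = nn.bce_with_logits(
            _take_rows(cat_logits, sel), tgt)
        if len(pos):
            reg_tgt = encode_boxes(all_anchors[pos], gt.boxes[best_gt[pos]])
            losses["rpn_box"] = nn.smooth_l1(
                _take_rows(cat_deltas, pos), reg_tgt, beta=1.0 / 9.0,
                normalizer=max(len(sel), 1))

    # ---- proposals + RoI targets
    proposals, _ = model.propose(logits, deltas, anchors, (H, W),
                                 training=True)
    if len(gt.boxes):
        extra = [proposals, gt.boxes]
        for _ in range(det.train_gt_jitter):
            wh = np.stack([gt.boxes[:, 2] - gt.boxes[:, 0],
                           gt.boxes[:, 3] - gt.boxes[:, 1]], axis=1)
            noise = rng.normal(0, det.train_gt_jitter_frac,
                               (len(gt.boxes), 4))
            jit = gt.boxes + noise * np.concatenate([wh, wh], axis=1)
            extra.append(clip_boxes(jit, H, W))
        proposals = np.concatenate(extra).astype(np.float32)
        ok = ((proposals[:, 2] - proposals[:, 0]) >= det.min_box_size) \
            & ((proposals[:, 3] - proposals[:, 1]) >= det.min_box_size)
        proposals = proposals[ok]
    if len(proposals) == 0:
        return losses
    if len(gt.boxes):
        ious = box_iou_xyxy(proposals, gt.boxes)
        best_gt = ious.argmax(axis=1)
        best_iou = ious[np.arange(len(proposals)), best_gt]
        fg = np.flatnonzero(best_iou >= det.roi_fg_iou)
        bg = np.flatnonzero(best_iou < det.roi_fg_iou)
    else:
        fg = np.zeros(0, np.int64)
        bg = np.arange(len(proposals))
        best_gt = np.zeros(len(proposals), np.int64)
    pos, neg = _sample(fg, bg, det.roi_batch, det.roi_pos_frac, rng)
    rois = np.concatenate([proposals[pos], proposals[neg]])
    roi_labels = np.concatenate([gt.labels[best_gt[pos]]
                                 if len(pos) else np.zeros(0, np.int64),
                                 np.zeros(len(neg), np.int64)])
    patches = model.roi_features(pyramid, rois, 7)
    cls_logits, box_deltas = model.box_head(patches)
    losses["roi_cls"] = nn.softmax_cross_entropy(cls_logits, roi_labels)
    if len(pos):
        reg_tgt = encode_boxes(rois[:len(pos)], gt.boxes[best_gt[pos]])
        k = det.num_classes + 1
        nd = box_deltas.shape[0]
        deltas_k = nn.reshape(box_deltas, (nd, k, 4))
        rows = np.arange(len(pos))
        sel_deltas = _take_rows(
            nn.reshape(deltas_k, (nd * k, 4)),
            rows * k + roi_labels[:len(pos)])
        losses["roi_box"] = nn.smooth_l1(sel_deltas, reg_tgt,
                                         normalizer=max(len(rois), 1) * 4)
        # ---- mask loss on positive rois
        mpatches = model.roi_features(pyramid, rois[:len(pos)], 14)
        mlogits = model.mask_head(mpatches)
        msize = det.mask_size
        targets = np.stack([
            _mask_target(gt.masks[best_gt[p]], rois[i], msize)
            for i, p in enumerate(pos)])
        npos = len(pos)
        sel_masks = _take_rows(
            nn.reshape(mlogits, (npos * det.num_classes, msize, msize)),
            np.arange(npos) * det.num_classes
            + (roi_labels[:npos] - 1))
        losses["mask"] = nn.bce_with_logits(sel_masks, targets)
    return losses


def train(dataset: CocoDataset, pixels: dict[int, np.ndarray],
          model_cfg: ModelConfig | None = None,
          tc: TrainConfig | None = None,
          out_dir: str | pathlib.Path | None = None,
          model: MaskRCNN | None = None
          ) -> tuple[MaskRCNN, list[dict]]:
    """Optimise the multi-task loss with SGD; returns model + epoch log."""
    tc = tc or TrainConfig()
    if not dataset.images:
        raise ValueError("training split is empty")
    model = model or MaskRCNN(model_cfg, seed=tc.seed)
    gts = ground_truth_from_coco(dataset)
    rng = np.random.default_rng(tc.seed + 1)
    opt = nn.SGD(model.parameters(), lr=tc.base_lr, momentum=tc.momentum,
                 weight_decay=tc.weight_decay,
                 max_grad_norm=tc.max_grad_norm)
    img_ids = [im["id"] for im in dataset.images]
    log: list[dict] = []
    step = 0
    done = False
    lr_base = tc.base_lr
    for epoch in range(tc.epochs):
        if done:
            break
        if epoch in tc.lr_decay_epochs:
            lr_base *= tc.lr_decay_factor
        order = rng.permutation(img_ids)
        epoch_losses: list[float] = []
        t0 = time.time()
        for start in range(0, len(order), tc.batch_size):
            batch = order[start:start + tc.batch_size]
            if tc.warmup_steps > 0 and step < tc.warmup_steps:
                opt.lr = lr_base * (0.1 + 0.9 * step / tc.warmup_steps)
            else:
                opt.lr = lr_base
            opt.zero_grad()
            batch_total = 0.0
            for img_id in batch:
                img = prepare_image(pixels[img_id])
                losses = compute_losses(model, img, gts[img_id], rng)
                if not losses:
                    continue
                total = None
                for v in losses.values():
                    total = v if total is None else total + v
                total = total * (1.0 / len(batch))
                if not np.isfinite(total.data):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch} step {step}: "
                        + str({k: float(v.data) for k, v in losses.items()}))
                total.backward()
                batch_total += float(total.data) * len(batch)
            opt.step()
            epoch_losses.append(batch_total / max(len(batch), 1))
            step += 1
            if tc.max_steps is not None and step >= tc.max_steps:
                done = True
                break
        rec = {"epoch": epoch, "loss": float(np.mean(epoch_losses)),
               "lr": opt.lr, "steps": step,
               "seconds": round(time.time() - t0, 2), "seed": tc.seed}
        log.append(rec)
        if out_dir is not None:
            out = pathlib.Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            with open(out / "losses.jsonl", "a") as fh:
                fh.write(json.dumps(rec) + "\n")
    if out_dir is not None:
        save_checkpoint(model, tc, pathlib.Path(out_dir) / "checkpoint.npz")
    return model, log


def save_checkpoint(model: MaskRCNN, tc: TrainConfig,
                    path: str | pathlib.Path):
    meta = {"model": dataclasses.asdict(model.cfg),
            "train": dataclasses.asdict(tc)}
    np.savez(path, __config__=json.dumps(meta, default=list),
             **model.state_dict())


def load_checkpoint(path: str | pathlib.Path) -> MaskRCNN:
    from .config import model_config_from_dict
    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__config__"]))
    cfg = model_config_from_dict(meta["model"])
    model = MaskRCNN(cfg)
    state = {k: data[k] for k in data.files if k != "__config__"}
    model.load_state_dict(state)
    return model


# -- inference ------------------------------------------------------------

def paste_mask(mask_prob: np.ndarray, box: np.ndarray, height: int,
               width: int, thresh: float = 0.5) -> np.ndarray:
    """Resize a mask-head probability patch into image space."""
    x1, y1, x2, y2 = box
    x1i, y1i = int(np.floor(x1)), int(np.floor(y1))
    x2i, y2i = min(int(np.ceil(x2)), width), min(int(np.ceil(y2)), height)
    w, h = max(x2i - x1i, 1), max(y2i - y1i, 1)
    img = Image.fromarray((mask_prob * 255).astype(np.uint8))
    patch = np.asarray(img.resize((w, h), Image.BILINEAR)) / 255.0
    out = np.zeros((height, width), dtype=bool)
    out[max(y1i, 0):y1i + h, max(x1i, 0):x1i + w] = \
        patch[:h - max(-y1i, 0), :w - max(-x1i, 0)] >= thresh
    return out


def predict(images: dict[int, np.ndarray], model: MaskRCNN,
            score_thresh: float | None = None,
            mask_thresh: float = 0.5) -> dict[int, list[dict]]:
    """Per-image detections: box (xywh), score, category_id, mask."""
    det = model.cfg.detector
    score_thresh = det.score_thresh if score_thresh is None else score_thresh
    results: dict[int, list[dict]] = {}
    with nn.no_grad():
        for img_id, pixels in images.items():
            img = prepare_image(pixels)
            H, W = img.shape[1:]
            pyramid = model.extract_pyramid(Tensor(img[None]))
            logits, deltas, anchors = model.rpn_forward(pyramid, (H, W))
            proposals, _ = model.propose(logits, deltas, anchors, (H, W),
                                         training=False)
            dets: list[dict] = []
            if len(proposals):
                patches = model.roi_features(pyramid, proposals, 7)
                cls_logits, box_deltas = model.box_head(patches)
                probs = nn.softmax(cls_logits, axis=1).data
                k = det.num_classes + 1
                all_boxes, all_scores, all_cats = [], [], []
                deltas_np = box_deltas.data.reshape(len(proposals), k, 4)
                for c in range(1, k):
                    scores_c = probs[:, c]
                    keep = scores_c >= score_thresh
                    if not keep.any():
                        continue
                    boxes_c = decode_boxes(proposals[keep],
                                           deltas_np[keep, c])
                    boxes_c = clip_boxes(boxes_c, H, W)
                    ok = ((boxes_c[:, 2] - boxes_c[:, 0]) >= 1) \
                        & ((boxes_c[:, 3] - boxes_c[:, 1]) >= 1)
                    boxes_c, sc = boxes_c[ok], scores_c[keep][ok]
                    if len(boxes_c) == 0:
                        continue
                    kept = nms(boxes_c, sc, det.nms_thresh)
                    all_boxes.append(boxes_c[kept])
                    all_scores.append(sc[kept])
                    all_cats.append(np.full(len(kept), c))
                if all_boxes:
                    boxes = np.concatenate(all_boxes)
                    scores = np.concatenate(all_scores)
                    cats = np.concatenate(all_cats)
                    order = np.argsort(-scores,
                                       kind="mergesort")[:det.max_detections]
                    boxes, scores, cats = boxes[order], scores[order], \
                        cats[order]
                    mpatches = model.roi_features(pyramid, boxes, 14)
                    mlogits = model.mask_head(mpatches)
                    mprobs = 1.0 / (1.0 + np.exp(-mlogits.data))
                    for i in range(len(boxes)):
                        x1, y1, x2, y2 = boxes[i]
                        mask = paste_mask(mprobs[i, cats[i] - 1], boxes[i],
                                          H, W, mask_thresh)
                        dets.append({
                            "category_id": int(cats[i]),
                            "score": float(scores[i]),
                            "bbox": [float(x1), float(y1),
                                     float(x2 - x1), float(y2 - y1)],
                            "mask": mask,
                        })
            results[img_id] = dets
    return results


def detections_to_coco_results(results: dict[int, list[dict]]) -> list[dict]:
    out = []
    for img_id, dets in results.items():
        for d in dets:
            out.append({
                "image_id": img_id,
                "category_id": d["category_id"],
                "bbox": [round(v, 2) for v in d["bbox"]],
                "score": d["score"],
                "segmentation": rle_encode(d["mask"]),
            })
    return out
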