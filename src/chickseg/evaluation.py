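"""COCO-style detection/segmentation metrics.

Implements the standard COCO protocol: greedy score-ordered one-to-one
matching per category at IoU thresholds 0.50:0.05:0.95, 101-point
interpolated precision, area-banded AP/AR and detection caps.  The eight
reported summary numbers are AP, AP50, AP75, AP_M, AP_L, AR10, AR_M and
AR_L; birds image as medium (32^2-96^2 px^2) or large (>96^2 px^2)
objects, so the small band is computed internally but not reported.
Empty bands carry the conventional -1 sentinel and are excluded from
means.

Masks travel either as dense boolean arrays or as uncompressed
column-major run-length encodings (the COCO 'counts' convention); IoU is
evaluated on dense pixel counts.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .dataset import CocoDataset, rasterize_polygons

IOU_THRESHOLDS = np.round(np.arange(0.5, 1.0, 0.05), 2)
RECALL_THRESHOLDS = np.linspace(0.0, 1.0, 101)

AREA_BANDS = {
    "all": (0.0, 1e10),
    "small": (0.0, 32.0 ** 2),
    "medium": (32.0 ** 2, 96.0 ** 2),
    "large": (96.0 ** 2, 1e10),
}


@dataclasses.dataclass
class MatchConfig:
    iou_thresholds: np.ndarray = dataclasses.field(
        default_factory=lambda: IOU_THRESHOLDS.copy())
    area_bands: dict = dataclasses.field(
        default_factory=lambda: dict(AREA_BANDS))
    max_dets: tuple[int, ...] = (10, 100)
    iou_mode: str = "bbox"          # 'bbox' | 'segm'


@dataclasses.dataclass
class MetricsReport:
    ap: float
    ap50: float
    ap75: float
    ap_m: float
    ap_l: float
    ar10: float
    ar_m: float
    ar_l: float
    per_category_ap: dict[str, float] = dataclasses.field(
        default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def summary_values(self) -> list[float]:
        return [self.ap, self.ap50, self.ap75, self.ap_m, self.ap_l,
                self.ar10, self.ar_m, self.ar_l]


# -- RLE utilities --------------------------------------------------------

def rle_encode(mask: np.ndarray) -> dict:
    """Column-major uncompressed RLE of a boolean mask (COCO 'counts')."""
    m = np.asarray(mask, dtype=bool)
    flat = m.T.ravel()
    # runs of equal values, starting with a (possibly zero-length) 0-run
    change = np.flatnonzero(flat[1:] != flat[:-1]) + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    counts = np.diff(bounds).tolist()
    if flat.size and flat[0]:
        counts = [0] + counts
    return {"size": [int(m.shape[0]), int(m.shape[1])], "counts": counts}


def rle_decode(rle: Mapping) -> np.ndarray:
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for c in rle["counts"]:
        if val:
            flat[pos:pos + c] = True
        pos += c
        val = not val
    return flat.reshape(w, h).T


def rle_area(rle: Mapping) -> int:
    return int(sum(rle["counts"][1::2]))


def _to_mask(seg, height: int | None = None, width: int | None = None
             ) -> np.ndarray:
    """Accept dense array, RLE dict, or COCO polygon list."""
    if isinstance(seg, np.ndarray):
        return seg.astype(bool)
    if isinstance(seg, Mapping):
        return rle_decode(seg)
    polys = [np.asarray(p, dtype=np.float64).reshape(-1, 2) for p in seg]
    if height is None or width is None:
        raise ValueError("polygon segmentation needs image height/width")
    return rasterize_polygons(polys, height, width)


# -- IoU ------------------------------------------------------------------

def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of [x, y, w, h] boxes with continuous areas."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    ax1, ay1 = a[:, 0], a[:, 1]
    ax2, ay2 = a[:, 0] + a[:, 2], a[:, 1] + a[:, 3]
    bx1, by1 = b[:, 0], b[:, 1]
    bx2, by2 = b[:, 0] + b[:, 2], b[:, 1] + b[:, 3]
    ix = np.maximum(0.0, np.minimum(ax2[:, None], bx2[None, :])
                    - np.maximum(ax1[:, None], bx1[None, :]))
    iy = np.maximum(0.0, np.minimum(ay2[:, None], by2[None, :])
                    - np.maximum(ay1[:, None], by1[None, :]))
    inter = ix * iy
    area_a = (a[:, 2] * a[:, 3])[:, None]
    area_b = (b[:, 2] * b[:, 3])[None, :]
    union = area_a + area_b - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def mask_iou_matrix(a: Sequence[np.ndarray], b: Sequence[np.ndarray]
                    ) -> np.ndarray:
    """Pairwise IoU of boolean masks by pixel counting."""
    if len(a) == 0 or len(b) == 0:
        return np.zeros((len(a), len(b)))
    A = np.stack([np.asarray(m, dtype=bool).ravel() for m in a])
    B = np.stack([np.asarray(m, dtype=bool).ravel() for m in b])
    inter = (A.astype(np.float64) @ B.T.astype(np.float64))
    area_a = A.sum(axis=1)[:, None].astype(np.float64)
    area_b = B.sum(axis=1)[None, :].astype(np.float64)
    union = area_a + area_b - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def pairwise_iou(a, b, mode: str = "bbox") -> np.ndarray:
    if mode == "bbox":
        return box_iou_matrix(a, b)
    if mode == "segm":
        return mask_iou_matrix(a, b)
    raise ValueError(f"unknown iou mode {mode!r}")


# -- matching + accumulation ---------------------------------------------

def match_detections(det_scores: np.ndarray, ious: np.ndarray,
                     gt_ignore: np.ndarray, det_areas: np.ndarray,
                     iou_thresholds: np.ndarray, area_rng: tuple,
                     max_det: int):
    """Greedy one-to-one matching, COCO protocol.

    Detections are taken in descending-score order (stable; index breaks
    ties), each claiming the highest-IoU unmatched truth above the
    threshold; non-ignored truths are preferred over ignored ones.
    Returns (dt_matched, dt_ignore, gt_matched) per threshold.
    """
    T = len(iou_thresholds)
    order = np.argsort(-det_scores, kind="mergesort")[:max_det]
    nd, ng = len(order), ious.shape[1]
    gt_order = np.argsort(gt_ignore, kind="mergesort")   # real truths first
    dtm = np.zeros((T, nd), dtype=np.int64) - 1
    gtm = np.zeros((T, ng), dtype=np.int64) - 1
    dt_ig = np.zeros((T, nd), dtype=bool)
    for ti, t in enumerate(iou_thresholds):
        for di, d in enumerate(order):
            best = min(t, 1 - 1e-10)
            m = -1
            for g in gt_order:
                if gtm[ti, g] >= 0:
                    continue
                if m > -1 and not gt_ignore[m] and gt_ignore[g]:
                    break
                if ious[d, g] < best:
                    continue
                best = ious[d, g]
                m = g
            if m >= 0:
                dtm[ti, di] = m
                gtm[ti, m] = d
                dt_ig[ti, di] = gt_ignore[m]
        outside = (det_areas[order] < area_rng[0]) \
            | (det_areas[order] > area_rng[1])
        dt_ig[ti] = dt_ig[ti] | ((dtm[ti] == -1) & outside)
    return order, dtm, dt_ig, gtm


def _gather(per_image: dict, img_ids, cat_id, mode):
    """Collect detections/truths of one category across images."""
    entries = []
    for img_id in img_ids:
        entries.append(per_image.get((img_id, cat_id),
                                     ([], [], [], [])))
    return entries


class CocoEvaluator:
    """Evaluate COCO-results-style predictions against a CocoDataset."""

    def __init__(self, gt: CocoDataset, mode: str = "bbox",
                 cfg: MatchConfig | None = None):
        if mode not in ("bbox", "segm"):
            raise ValueError("mode must be 'bbox' or 'segm'")
        self.gt = gt
        self.mode = mode
        self.cfg = cfg or MatchConfig(iou_mode=mode)
        self.img_meta = {im["id"]: im for im in gt.images}
        self.cat_ids = [c["id"] for c in gt.categories]
        self.cat_names = {c["id"]: c["name"] for c in gt.categories}
        self.gt_by_key: dict[tuple, list[dict]] = {}
        for a in gt.annotations:
            self.gt_by_key.setdefault((a["image_id"], a["category_id"]),
                                      []).append(a)

    # ---- per-image structures
    def _gt_repr(self, ann: dict):
        im = self.img_meta[ann["image_id"]]
        if self.mode == "bbox":
            return ann["bbox"]
        return _to_mask(ann["segmentation"], im["height"], im["width"])

    def _dt_repr(self, det: dict):
        im = self.img_meta[det["image_id"]]
        if self.mode == "bbox":
            return det["bbox"]
        return _to_mask(det["segmentation"], im["height"], im["width"])

    def _dt_area(self, det: dict, repr_) -> float:
        if self.mode == "bbox":
            return float(repr_[2] * repr_[3])
        return float(np.asarray(repr_).sum())

    def evaluate(self, predictions: Sequence[dict]) -> MetricsReport:
        cfg = self.cfg
        img_ids = [im["id"] for im in self.gt.images]
        dt_by_key: dict[tuple, list[dict]] = {}
        for d in predictions:
            dt_by_key.setdefault((d["image_id"], d["category_id"]),
                                 []).append(d)

        bands = {k: cfg.area_bands[k]
                 for k in ("all", "medium", "large", "small")}
        max_det_all = max(cfg.max_dets)
        T = len(cfg.iou_thresholds)
        R = len(RECALL_THRESHOLDS)
        K = len(self.cat_ids)
        band_names = list(bands)
        A, M = len(band_names), len(cfg.max_dets)
        precision = -np.ones((T, R, K, A, M))
        recall = -np.ones((T, K, A, M))

        # per (image, cat): compute ious once at the largest det cap
        for ki, cat in enumerate(self.cat_ids):
            # cache per-image matches per area band
            img_entries = []
            for img_id in img_ids:
                gts = self.gt_by_key.get((img_id, cat), [])
                dts = sorted(dt_by_key.get((img_id, cat), []),
                             key=lambda d: -d["score"])[:max_det_all]
                if not gts and not dts:
                    img_entries.append(None)
                    continue
                g_repr = [self._gt_repr(g) for g in gts]
                d_repr = [self._dt_repr(d) for d in dts]
                ious = pairwise_iou(d_repr, g_repr, self.mode) \
                    if gts and dts else np.zeros((len(dts), len(gts)))
                img_entries.append({
                    "scores": np.array([d["score"] for d in dts]),
                    "gt_areas": np.array([g["area"] for g in gts],
                                         dtype=np.float64),
                    "dt_areas": np.array([self._dt_area(d, r) for d, r
                                          in zip(dts, d_repr)]),
                    "ious": ious,
                })

            for ai, band in enumerate(band_names):
                rng_ = bands[band]
                for mi, mdet in enumerate(cfg.max_dets):
                    all_scores, all_tp, all_ig = [], [], []
                    npig = 0
                    for entry in img_entries:
                        if entry is None:
                            continue
                        gt_ig = (entry["gt_areas"] < rng_[0]) \
                            | (entry["gt_areas"] > rng_[1])
                        order, dtm, dt_ig, _ = match_detections(
                            entry["scores"], entry["ious"], gt_ig,
                            entry["dt_areas"], cfg.iou_thresholds,
                            rng_, mdet)
                        npig += int((~gt_ig).sum())
                        all_scores.append(entry["scores"][order])
                        all_tp.append(dtm >= 0)
                        all_ig.append(dt_ig)
                    if npig == 0:
                        continue
                    if all_scores:
                        scores = np.concatenate(all_scores)
                        tps = np.concatenate(all_tp, axis=1)
                        igs = np.concatenate(all_ig, axis=1)
                        o = np.argsort(-scores, kind="mergesort")
                        tps, igs = tps[:, o], igs[:, o]
                    else:
                        tps = np.zeros((T, 0), dtype=bool)
                        igs = np.zeros((T, 0), dtype=bool)
                    tp = np.cumsum(tps & ~igs, axis=1).astype(np.float64)
                    fp = np.cumsum(~tps & ~igs, axis=1).astype(np.float64)
                    for ti in range(T):
                        tpr, fpr = tp[ti], fp[ti]
                        nd = len(tpr)
                        rc = tpr / npig
                        pr = tpr / (tpr + fpr + np.spacing(1))
                        recall[ti, ki, ai, mi] = rc[-1] if nd else 0.0
                        q = np.zeros(R)
                        # precision envelope (monotone from the right)
                        pr = pr.tolist()
                        for i in range(nd - 1, 0, -1):
                            if pr[i] > pr[i - 1]:
                                pr[i - 1] = pr[i]
                        inds = np.searchsorted(rc, RECALL_THRESHOLDS,
                                               side="left")
                        for ri, pi in enumerate(inds):
                            if pi < nd:
                                q[ri] = pr[pi]
                        precision[ti, :, ki, ai, mi] = q
        self.precision = precision
        self.recall = recall
        self.band_names = band_names
        return self._summarize()

    # ---- summary
    def _mean(self, x: np.ndarray) -> float:
        valid = x[x > -1]
        return float(valid.mean()) if valid.size else -1.0

    def _ap(self, iou_thr: float | None = None, band: str = "all",
            max_det: int = 100, cat_index: int | None = None) -> float:
        ai = self.band_names.index(band)
        mi = list(self.cfg.max_dets).index(max_det)
        p = self.precision[:, :, :, ai, mi]
        if iou_thr is not None:
            ti = int(np.flatnonzero(
                np.isclose(self.cfg.iou_thresholds, iou_thr))[0])
            p = p[ti:ti + 1]
        if cat_index is not None:
            p = p[:, :, cat_index:cat_index + 1]
        return self._mean(p)

    def _ar(self, band: str = "all", max_det: int = 100) -> float:
        ai = self.band_names.index(band)
        mi = list(self.cfg.max_dets).index(max_det)
        return self._mean(self.recall[:, :, ai, mi])

    def _summarize(self) -> MetricsReport:
        md = max(self.cfg.max_dets)
        md_small = min(self.cfg.max_dets)
        per_cat = {}
        for ki, cat in enumerate(self.cat_ids):
            per_cat[self.cat_names[cat]] = self._ap(
                iou_thr=0.5, max_det=md, cat_index=ki)
        return MetricsReport(
            ap=self._ap(max_det=md),
            ap50=self._ap(iou_thr=0.5, max_det=md),
            ap75=self._ap(iou_thr=0.75, max_det=md),
            ap_m=self._ap(band="medium", max_det=md),
            ap_l=self._ap(band="large", max_det=md),
            ar10=self._ar(max_det=md_small),
            ar_m=self._ar(band="medium", max_det=md),
            ar_l=self._ar(band="large", max_det=md),
            per_category_ap=per_cat,
        )


def evaluate_predictions(gt: CocoDataset, predictions: Sequence[dict],
                         mode: str = "bbox",
                         cfg: MatchConfig | None = None) -> MetricsReport:
    """One-call evaluation: predictions in COCO results form
    ({image_id, category_id, bbox, score, segmentation})."""
    return CocoEvaluator(gt, mode=mode, cfg=cfg).evaluate(predictions)


def per_category_accuracy(gt: CocoDataset, predictions: Sequence[dict],
                          mode: str = "segm") -> dict[str, float]:
    """Per-category segmentation AP at IoU 0.5 (the per-class accuracy
    figure reported for the four aggregation states)."""
    report = evaluate_predictions(gt, predictions, mode=mode)
    return report.per_category_ap


def predictions_from_ground_truth(gt: CocoDataset, score: float = 1.0
                                  ) -> list[dict]:
    """Turn ground truth into a perfect prediction set (for calibration)."""
    preds = []
    for a in gt.annotations:
        preds.append({
            "image_id": a["image_id"],
            "category_id": a["category_id"],
            "bbox": list(a["bbox"]),
            "score": score,
            "segmentation": a["segmentation"],
        })
    return preds
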