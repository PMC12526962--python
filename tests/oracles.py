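"""Independent straight-line oracles used by the test suite.

These are deliberately naive reimplementations (explicit loops, dense
pixel masks, no vectorisation in the protocol logic) kept separate from
the package so that tests compare two independent routes to the same
numbers.  Pairwise IoU matrices are computed once per (image, category)
cell — by the oracle's own loops — and reused across thresholds.
"""

from __future__ import annotations

import numpy as np

IOU_THRS = [round(0.5 + 0.05 * i, 2) for i in range(10)]
# the protocol's 0:0.01:1 recall grid; generated the same way as the
# canonical implementation so float representation matches exactly
REC_THRS = np.linspace(0.0, 1.0, 101).tolist()
BANDS = {"all": (0.0, 1e10), "small": (0.0, 1024.0),
         "medium": (1024.0, 9216.0), "large": (9216.0, 1e10)}


def iou_box(a, b):
    ax1, ay1, ax2, ay2 = a[0], a[1], a[0] + a[2], a[1] + a[3]
    bx1, by1, bx2, by2 = b[0], b[1], b[0] + b[2], b[1] + b[3]
    iw = max(0.0, min(ax2, bx2) - max(ax1, bx1))
    ih = max(0.0, min(ay2, by2) - max(ay1, by1))
    inter = iw * ih
    union = a[2] * a[3] + b[2] * b[3] - inter
    return inter / union if union > 0 else 0.0


def iou_mask(a, b):
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return inter / union if union > 0 else 0.0


def _match_one_image(cell, thr, band, max_det, mode):
    """COCO-protocol greedy matching for one (image, category) cell.

    Returns per-detection (score, is_tp, ignored) records plus the
    number of non-ignored truths.
    """
    lo, hi = BANDS[band]
    dt_order = sorted(range(len(cell["dt"])),
                      key=lambda i: -cell["dt"][i]["score"])[:max_det]
    gts = cell["gt"]
    gt_ig = [g["area"] < lo or g["area"] > hi for g in gts]
    gt_idx = sorted(range(len(gts)), key=lambda i: gt_ig[i])
    matched_gt = set()
    out = []
    for di in dt_order:
        d = cell["dt"][di]
        best_iou = min(thr, 1 - 1e-10)
        best_g = -1
        for g in gt_idx:
            if g in matched_gt:
                continue
            if best_g > -1 and not gt_ig[best_g] and gt_ig[g]:
                break
            iou = cell["iou"][di][g]
            if iou < best_iou:
                continue
            best_iou = iou
            best_g = g
        if best_g >= 0:
            matched_gt.add(best_g)
            out.append((d["score"], True, gt_ig[best_g]))
        else:
            outside = d["area"] < lo or d["area"] > hi
            out.append((d["score"], False, outside))
    npig = sum(1 for ig in gt_ig if not ig)
    return out, npig


def _pr_curve(records, npig):
    """101-point interpolated precision and final recall."""
    records = sorted(records, key=lambda r: -r[0])
    tp = fp = 0
    rc, pr = [], []
    for _score, is_tp, ignored in records:
        if ignored:
            continue
        if is_tp:
            tp += 1
        else:
            fp += 1
        rc.append(tp / npig)
        pr.append(tp / (tp + fp))
    # monotone envelope from the right
    for i in range(len(pr) - 2, -1, -1):
        pr[i] = max(pr[i], pr[i + 1])
    q = []
    for r in REC_THRS:
        idx = next((i for i, v in enumerate(rc) if v >= r), None)
        q.append(pr[idx] if idx is not None else 0.0)
    final_rc = rc[-1] if rc else 0.0
    return q, final_rc


def _build_cells(gt_dataset, predictions, mode):
    from chickseg.dataset import rasterize_polygons
    from chickseg.evaluation import rle_decode

    img_meta = {im["id"]: im for im in gt_dataset.images}

    def gt_repr(a):
        if mode == "bbox":
            return a["bbox"]
        im = img_meta[a["image_id"]]
        return rasterize_polygons(
            [np.asarray(p).reshape(-1, 2) for p in a["segmentation"]],
            im["height"], im["width"])

    def dt_repr(d):
        if mode == "bbox":
            return d["bbox"]
        seg = d["segmentation"]
        if isinstance(seg, np.ndarray):
            return seg.astype(bool)
        if isinstance(seg, dict):
            return rle_decode(seg)
        im = img_meta[d["image_id"]]
        return rasterize_polygons(
            [np.asarray(p).reshape(-1, 2) for p in seg],
            im["height"], im["width"])

    cells = {}
    for a in gt_dataset.annotations:
        cells.setdefault((a["image_id"], a["category_id"]),
                         {"gt": [], "dt": []})["gt"].append(
            {"repr": gt_repr(a), "area": a["area"]})
    for d in predictions:
        r = dt_repr(d)
        area = (r[2] * r[3]) if mode == "bbox" else float(np.sum(r))
        cells.setdefault((d["image_id"], d["category_id"]),
                         {"gt": [], "dt": []})["dt"].append(
            {"repr": r, "score": d["score"], "area": area})
    fn = iou_box if mode == "bbox" else iou_mask
    for cell in cells.values():
        cell["iou"] = [[fn(d["repr"], g["repr"]) for g in cell["gt"]]
                       for d in cell["dt"]]
    return cells, img_meta


def evaluate_reference(gt_dataset, predictions, mode):
    """The eight summary metrics, computed the slow explicit way."""
    cells, img_meta = _build_cells(gt_dataset, predictions, mode)
    cat_ids = [c["id"] for c in gt_dataset.categories]

    def ap(thr_list, band, max_det):
        vals = []
        for cat in cat_ids:
            for thr in thr_list:
                records, npig = [], 0
                for img_id in img_meta:
                    cell = cells.get((img_id, cat))
                    if cell is None:
                        continue
                    recs, n = _match_one_image(cell, thr, band, max_det,
                                               mode)
                    records.extend(recs)
                    npig += n
                if npig == 0:
                    continue
                q, _ = _pr_curve(records, npig)
                vals.extend(q)
        return float(np.mean(vals)) if vals else -1.0

    def ar(band, max_det):
        vals = []
        for cat in cat_ids:
            for thr in IOU_THRS:
                records, npig = [], 0
                for img_id in img_meta:
                    cell = cells.get((img_id, cat))
                    if cell is None:
                        continue
                    recs, n = _match_one_image(cell, thr, band, max_det,
                                               mode)
                    records.extend(recs)
                    npig += n
                if npig == 0:
                    continue
                _, rc = _pr_curve(records, npig)
                vals.append(rc)
        return float(np.mean(vals)) if vals else -1.0

    return {
        "ap": ap(IOU_THRS, "all", 100),
        "ap50": ap([0.5], "all", 100),
        "ap75": ap([0.75], "all", 100),
        "ap_m": ap(IOU_THRS, "medium", 100),
        "ap_l": ap(IOU_THRS, "large", 100),
        "ar10": ar("all", 10),
        "ar_m": ar("medium", 100),
        "ar_l": ar("large", 100),
    }


def perturbed_predictions(dataset, pixels_hw, rng, drop_prob=0.2,
                          fp_prob=0.3, jitter=6.0):
    """Randomised imperfect predictions derived from ground truth:
    jittered boxes/masks with random scores, some truths dropped, some
    false positives added."""
    from chickseg.dataset import rasterize_polygons

    preds = []
    img_meta = {im["id"]: im for im in dataset.images}
    for a in dataset.annotations:
        if rng.random() < drop_prob:
            continue
        im = img_meta[a["image_id"]]
        h, w = im["height"], im["width"]
        dx, dy = rng.normal(0, jitter, 2)
        polys = [np.asarray(p).reshape(-1, 2) + [dx, dy]
                 for p in a["segmentation"]]
        for p in polys:
            p[:, 0] = np.clip(p[:, 0], 0, w)
            p[:, 1] = np.clip(p[:, 1], 0, h)
        mask = rasterize_polygons(polys, h, w)
        if not mask.any():
            continue
        x, y, bw, bh = a["bbox"]
        preds.append({
            "image_id": a["image_id"],
            "category_id": (a["category_id"] if rng.random() > 0.1
                            else int(rng.integers(1, 5))),
            "bbox": [x + dx, y + dy, max(bw + rng.normal(0, jitter), 2.0),
                     max(bh + rng.normal(0, jitter), 2.0)],
            "score": float(rng.random()),
            "segmentation": mask,
        })
    for im in dataset.images:
        while rng.random() < fp_prob:
            h, w = im["height"], im["width"]
            bw, bh = rng.uniform(10, 120, 2)
            x = rng.uniform(0, w - bw)
            y = rng.uniform(0, h - bh)
            mask = np.zeros((h, w), dtype=bool)
            mask[int(y):int(y + bh), int(x):int(x + bw)] = True
            preds.append({
                "image_id": im["id"],
                "category_id": int(rng.integers(1, 5)),
                "bbox": [x, y, bw, bh],
                "score": float(rng.random()),
                "segmentation": mask,
            })
    return preds
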