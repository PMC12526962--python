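"""COCO dataset construction: Labelme ingestion, augmentation, splitting.

Four aggregation-state categories are used throughout, with fixed ids:

    1 chicken-half   an occluded single bird
    2 chicken-whole  an unoccluded single bird
    3 chicken-few    a small touching group (2-3 birds)
    4 chicken-many   a large touching group (4 or more)

Five augmentation operators are supported — horizontal mirror flip,
brightness gain, Gaussian noise, salt-and-pepper dots, and random shift —
and the geometric ones transform polygon annotations consistently with
the pixels.  Each operator applied once per image turns N originals into
6N images.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import logging
import pathlib
from typing import Iterable, Mapping, Sequence

import numpy as np
from skimage.draw import polygon as draw_polygon

logger = logging.getLogger(__name__)

CATEGORY_NAMES = ("chicken-half", "chicken-whole", "chicken-few",
                  "chicken-many")
CATEGORY_IDS = {name: i + 1 for i, name in enumerate(CATEGORY_NAMES)}

AUGMENTATION_OPS = ("mirror_flip", "brightness", "gaussian_noise",
                    "salt_pepper", "random_shift")


def coco_categories() -> list[dict]:
    return [{"id": i + 1, "name": n, "supercategory": "chicken"}
            for i, n in enumerate(CATEGORY_NAMES)]


@dataclasses.dataclass
class PolygonInstance:
    category: str
    vertices: np.ndarray          # (V, 2) float (x, y)
    image_id: int = 0

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 \
                or self.vertices.shape[0] < 3:
            raise ValueError("polygon needs >= 3 (x, y) vertices")
        if self.category not in CATEGORY_IDS:
            raise ValueError(f"unknown category {self.category!r}; "
                             f"expected one of {CATEGORY_NAMES}")


@dataclasses.dataclass
class AnnotatedImage:
    image: np.ndarray
    instances: list[PolygonInstance]
    source_id: str = ""


@dataclasses.dataclass
class CocoDataset:
    """COCO-semantics container (plain dicts, serialisable as-is)."""

    images: list[dict] = dataclasses.field(default_factory=list)
    annotations: list[dict] = dataclasses.field(default_factory=list)
    categories: list[dict] = dataclasses.field(default_factory=coco_categories)

    def to_dict(self) -> dict:
        return {"images": self.images, "annotations": self.annotations,
                "categories": self.categories}

    @classmethod
    def from_dict(cls, d: Mapping) -> "CocoDataset":
        return cls(images=list(d["images"]),
                   annotations=list(d["annotations"]),
                   categories=list(d["categories"]))

    def save(self, path: str | pathlib.Path):
        pathlib.Path(path).write_text(
            json.dumps(self.to_dict(), sort_keys=True,
                       separators=(",", ":")))

    @classmethod
    def load(cls, path: str | pathlib.Path) -> "CocoDataset":
        return cls.from_dict(json.loads(pathlib.Path(path).read_text()))

    def validate(self):
        """Check referential integrity, id uniqueness, category closure."""
        img_ids = [im["id"] for im in self.images]
        if len(set(img_ids)) != len(img_ids):
            raise ValueError("duplicate image ids")
        ann_ids = [a["id"] for a in self.annotations]
        if len(set(ann_ids)) != len(ann_ids):
            raise ValueError("duplicate annotation ids")
        cat_ids = {c["id"] for c in self.categories}
        img_set = set(img_ids)
        for a in self.annotations:
            if a["image_id"] not in img_set:
                raise ValueError(f"annotation {a['id']} references missing "
                                 f"image {a['image_id']}")
            if a["category_id"] not in cat_ids:
                raise ValueError(f"annotation {a['id']} has unknown "
                                 f"category {a['category_id']}")
        return self


@dataclasses.dataclass
class SplitSpec:
    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")
        if any(r <= 0 for r in self.ratios):
            raise ValueError("split ratios must be positive")


@dataclasses.dataclass
class AugmentParams:
    """Seed-controlled parameter ranges for the photometric/geometric ops."""

    brightness_gain: tuple[float, float] = (0.6, 1.4)
    noise_sigma: tuple[float, float] = (5.0, 15.0)
    salt_pepper_density: tuple[float, float] = (0.005, 0.02)
    shift_frac: float = 0.10
    min_clipped_area: float = 16.0


# -- geometry helpers -----------------------------------------------------

def rasterize_polygons(polys: Sequence[np.ndarray], height: int,
                       width: int) -> np.ndarray:
    """Fill one or more (V,2) xy-polygons into a boolean HxW mask.

    Vertices use the pixel-corner origin (pixel (r, c) spans
    [c, c+1] x [r, r+1]); the half-pixel shift converts to the
    centre-index space the scanline filler expects.
    """
    mask = np.zeros((height, width), dtype=bool)
    for p in polys:
        p = np.asarray(p, dtype=np.float64)
        rr, cc = draw_polygon(p[:, 1] - 0.5, p[:, 0] - 0.5,
                              shape=(height, width))
        mask[rr, cc] = True
    return mask


def polygon_bbox(polys: Sequence[np.ndarray]) -> list[float]:
    """Tight [x, y, w, h] box of the polygon vertex set."""
    pts = np.concatenate([np.asarray(p, dtype=np.float64) for p in polys])
    x0, y0 = pts.min(axis=0)
    x1, y1 = pts.max(axis=0)
    return [float(x0), float(y0), float(x1 - x0), float(y1 - y0)]


def _segmentation_to_polys(seg) -> list[np.ndarray]:
    return [np.asarray(s, dtype=np.float64).reshape(-1, 2) for s in seg]


def annotation_from_polys(polys: Sequence[np.ndarray], ann_id: int,
                          image_id: int, category_id: int,
                          height: int, width: int) -> dict:
    mask = rasterize_polygons(polys, height, width)
    return {
        "id": ann_id,
        "image_id": image_id,
        "category_id": category_id,
        "segmentation": [np.asarray(p).ravel().round(2).tolist()
                         for p in polys],
        "bbox": [round(v, 2) for v in polygon_bbox(polys)],
        "area": int(mask.sum()),
        "iscrowd": 0,
    }


# -- Labelme -> COCO ------------------------------------------------------

def labelme_to_coco(documents: Iterable[Mapping | str | pathlib.Path]
                    ) -> CocoDataset:
    """Convert Labelme-style polygon annotation documents to COCO.

    Each document (dict or JSON path) must carry ``imagePath``,
    ``imageHeight``/``imageWidth`` and ``shapes`` with polygon ``points``
    labelled from the four-category set.
    """
    ds = CocoDataset()
    ann_id = 1
    for img_id, doc in enumerate(documents, start=1):
        name = ""
        if isinstance(doc, (str, pathlib.Path)):
            name = str(doc)
            doc = json.loads(pathlib.Path(doc).read_text())
        h, w = int(doc["imageHeight"]), int(doc["imageWidth"])
        ds.images.append({
            "id": img_id,
            "file_name": doc.get("imagePath", f"image_{img_id:06d}.png"),
            "height": h,
            "width": w,
        })
        for shape in doc.get("shapes", []):
            label = shape["label"]
            if label not in CATEGORY_IDS:
                raise ValueError(
                    f"unknown label {label!r} in {name or 'document'} "
                    f"(expected one of {CATEGORY_NAMES})")
            pts = np.asarray(shape["points"], dtype=np.float64)
            if pts.ndim != 2 or pts.shape[0] < 3:
                raise ValueError(
                    f"degenerate polygon (<3 points) in {name or 'document'}")
            pts[:, 0] = np.clip(pts[:, 0], 0, w)
            pts[:, 1] = np.clip(pts[:, 1], 0, h)
            ds.annotations.append(annotation_from_polys(
                [pts], ann_id, img_id, CATEGORY_IDS[label], h, w))
            ann_id += 1
    return ds.validate()


# -- augmentation ---------------------------------------------------------

def apply_augmentation(item: AnnotatedImage, op_name: str, seed: int,
                       params: AugmentParams | None = None) -> AnnotatedImage:
    """Apply one augmentation operator; geometric ops transform polygons."""
    if op_name not in AUGMENTATION_OPS:
        raise ValueError(f"unknown augmentation {op_name!r}; "
                         f"expected one of {AUGMENTATION_OPS}")
    params = params or AugmentParams()
    rng = np.random.default_rng(seed)
    img = item.image
    h, w = img.shape[:2]

    if op_name == "mirror_flip":
        out_img = img[:, ::-1].copy()
        instances = [PolygonInstance(
            inst.category,
            np.column_stack([w - inst.vertices[:, 0], inst.vertices[:, 1]]),
            inst.image_id) for inst in item.instances]
        return AnnotatedImage(out_img, instances, item.source_id)

    if op_name == "brightness":
        gain = rng.uniform(*params.brightness_gain)
        out_img = np.clip(img.astype(np.float64) * gain, 0, 255)
        return AnnotatedImage(out_img.astype(img.dtype),
                              copy.deepcopy(item.instances), item.source_id)

    if op_name == "gaussian_noise":
        sigma = rng.uniform(*params.noise_sigma)
        out_img = np.clip(img.astype(np.float64)
                          + rng.normal(0, sigma, img.shape), 0, 255)
        return AnnotatedImage(out_img.astype(img.dtype),
                              copy.deepcopy(item.instances), item.source_id)

    if op_name == "salt_pepper":
        density = rng.uniform(*params.salt_pepper_density)
        out_img = img.copy()
        n_dots = int(round(density * h * w))
        ys = rng.integers(0, h, n_dots)
        xs = rng.integers(0, w, n_dots)
        vals = rng.integers(0, 2, n_dots) * 255
        if out_img.ndim == 3:
            out_img[ys, xs, :] = vals[:, None]
        else:
            out_img[ys, xs] = vals.astype(out_img.dtype)
        return AnnotatedImage(out_img, copy.deepcopy(item.instances),
                              item.source_id)

    # random_shift
    dx = int(rng.integers(-int(params.shift_frac * w),
                          int(params.shift_frac * w) + 1))
    dy = int(rng.integers(-int(params.shift_frac * h),
                          int(params.shift_frac * h) + 1))
    out_img = np.zeros_like(img)
    src_y = slice(max(0, -dy), min(h, h - dy))
    src_x = slice(max(0, -dx), min(w, w - dx))
    dst_y = slice(max(0, dy), min(h, h + dy))
    dst_x = slice(max(0, dx), min(w, w + dx))
    out_img[dst_y, dst_x] = img[src_y, src_x]
    instances = []
    for inst in item.instances:
        v = inst.vertices + np.array([dx, dy], dtype=np.float64)
        v[:, 0] = np.clip(v[:, 0], 0, w)
        v[:, 1] = np.clip(v[:, 1], 0, h)
        area = rasterize_polygons([v], h, w).sum()
        if area >= params.min_clipped_area:
            instances.append(PolygonInstance(inst.category, v, inst.image_id))
    if item.instances and not instances:
        logger.warning("random_shift (dx=%d, dy=%d) removed all instances "
                       "of %s", dx, dy, item.source_id or "image")
    return AnnotatedImage(out_img, instances, item.source_id)


def build_augmented_dataset(dataset: CocoDataset,
                            images: Mapping[int, np.ndarray],
                            seed: int,
                            params: AugmentParams | None = None
                            ) -> tuple[CocoDataset, dict[int, np.ndarray]]:
    """Every original image plus one copy per operator: 6x the images.

    ``images`` maps image id -> pixel array.  Returns the augmented
    dataset and its pixel store; all ids re-assigned uniquely.
    """
    if not dataset.images:
        raise ValueError("cannot augment an empty dataset")
    dataset.validate()
    params = params or AugmentParams()
    ann_by_img: dict[int, list[dict]] = {}
    for a in dataset.annotations:
        ann_by_img.setdefault(a["image_id"], []).append(a)
    cat_name = {c["id"]: c["name"] for c in dataset.categories}

    out = CocoDataset(categories=copy.deepcopy(dataset.categories))
    out_pixels: dict[int, np.ndarray] = {}
    new_img_id = 1
    new_ann_id = 1
    for rec in dataset.images:
        pix = np.asarray(images[rec["id"]])
        h, w = int(rec["height"]), int(rec["width"])
        item = AnnotatedImage(
            pix,
            [PolygonInstance(cat_name[a["category_id"]],
                             _segmentation_to_polys(a["segmentation"])[0],
                             rec["id"])
             for a in ann_by_img.get(rec["id"], [])],
            source_id=rec["file_name"])
        variants = [("orig", item)]
        for k, op in enumerate(AUGMENTATION_OPS):
            variants.append((op, apply_augmentation(
                item, op, seed=seed * 1000003 + rec["id"] * 7 + k,
                params=params)))
        stem = pathlib.Path(rec["file_name"]).stem
        for tag, var in variants:
            out.images.append({
                "id": new_img_id,
                "file_name": f"{stem}_{tag}.png",
                "height": h,
                "width": w,
                "source_id": rec["id"],
            })
            out_pixels[new_img_id] = var.image
            for inst in var.instances:
                out.annotations.append(annotation_from_polys(
                    [inst.vertices], new_ann_id, new_img_id,
                    CATEGORY_IDS[inst.category], h, w))
                new_ann_id += 1
            new_img_id += 1
    return out.validate(), out_pixels


# -- splitting ------------------------------------------------------------

def split_dataset(dataset: CocoDataset, spec: SplitSpec,
                  group_by_source: bool = False
                  ) -> tuple[CocoDataset, CocoDataset, CocoDataset]:
    """Shuffle images by seed and partition train/val/test.

    Counts are round(r_train*N) / round(r_val*N) / remainder.  With
    ``group_by_source`` images sharing a ``source_id`` (augmented copies
    of one original) travel together, preventing train/test leakage.
    """
    if len(dataset.images) < 3:
        raise ValueError("need at least 3 images to split")
    rng = np.random.default_rng(spec.seed)

    if group_by_source:
        keys = sorted({im.get("source_id", im["id"]) for im in dataset.images})
        order = [keys[i] for i in rng.permutation(len(keys))]
        n = len(order)
    else:
        order = [im["id"] for im in dataset.images]
        order = [order[i] for i in rng.permutation(len(order))]
        n = len(order)

    n_train = int(round(spec.ratios[0] * n))
    n_val = int(round(spec.ratios[1] * n))
    parts = (set(order[:n_train]), set(order[n_train:n_train + n_val]),
             set(order[n_train + n_val:]))

    def subset(keys: set) -> CocoDataset:
        if group_by_source:
            imgs = [im for im in dataset.images
                    if im.get("source_id", im["id"]) in keys]
        else:
            imgs = [im for im in dataset.images if im["id"] in keys]
        ids = {im["id"] for im in imgs}
        anns = [a for a in dataset.annotations if a["image_id"] in ids]
        return CocoDataset(images=copy.deepcopy(imgs),
                           annotations=copy.deepcopy(anns),
                           categories=copy.deepcopy(dataset.categories))

    return tuple(subset(p) for p in parts)
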