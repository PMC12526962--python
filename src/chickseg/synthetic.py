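"""Synthetic infrared scenes of caged birds for pipeline testing.

Warm bodies image as bright elliptical blobs on a cooler background;
cage bars appear as dark vertical occluders; sensor noise is Gaussian.
Touching blobs merge into contiguous high-heat regions, which is exactly
how aggregated birds present in real thermal footage, so annotation
follows the aggregation-state rule:

    isolated blob, mostly visible      -> chicken-whole
    isolated blob, >30% under bars     -> chicken-half
    touching group of 2-3 blobs        -> chicken-few
    touching group of 4 or more        -> chicken-many

Ground-truth polygons are traced from the pre-noise visible masks; the
stored truth masks are the rasterisation of those polygons, so polygons
and masks agree by construction.  Everything is a pure function of the
seed.  This is a stand-in for farm footage, not a radiometric model.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import measure

from .dataset import (CATEGORY_IDS, CocoDataset, PolygonInstance,
                      annotation_from_polys, rasterize_polygons)
from .keyframes import FrameSequence, GrayFrame


class PlacementError(RuntimeError):
    """Raised when blobs cannot be placed within bounds."""


@dataclasses.dataclass
class SceneSpec:
    image_size: tuple[int, int] = (512, 512)     # (W, H)
    n_blobs: int = 5
    blob_intensity_range: tuple[int, int] = (150, 235)
    blob_axes_range: tuple[float, float] = (18.0, 46.0)
    background_level: float = 60.0
    noise_sigma: float = 5.0
    occluder_bars: int = 3
    occluder_width: int = 6
    occluder_level: float = 35.0
    cluster_prob: float = 0.35
    occluded_fraction_threshold: float = 0.30
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.blob_intensity_range
        if not (0 <= lo <= hi <= 255):
            raise ValueError("blob intensities must lie in [0, 255]")
        if not 0 <= self.cluster_prob <= 1:
            raise ValueError("cluster_prob must lie in [0, 1]")


@dataclasses.dataclass
class GeneratedScene:
    image: np.ndarray                       # uint8 HxW
    instances: list[PolygonInstance]
    truth_masks: list[np.ndarray]           # boolean HxW, one per instance
    blob_masks: list[np.ndarray]            # per-blob pre-occlusion masks
    group_members: list[list[int]]          # blob indices per instance


def _ellipse_mask_and_heat(W, H, cx, cy, a, b, theta):
    """Boolean mask and a smooth heat profile of a rotated ellipse."""
    yy, xx = np.mgrid[0:H, 0:W]
    ct, st = np.cos(theta), np.sin(theta)
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    r2 = (u / a) ** 2 + (v / b) ** 2
    mask = r2 <= 1.0
    heat = np.clip(1.0 - 0.6 * r2, 0.0, 1.0)      # warm core, cooler rim
    return mask, heat * mask


def _trace_polygons(mask: np.ndarray, min_area: float = 16.0,
                    step: int = 2) -> list[np.ndarray]:
    """Trace a boolean mask into xy polygons (possibly several pieces)."""
    padded = np.pad(mask.astype(np.float64), 1)
    polys = []
    for contour in measure.find_contours(padded, 0.5):
        pts = contour[::step]
        if len(pts) < 3:
            continue
        xy = np.column_stack([pts[:, 1] - 1.0, pts[:, 0] - 1.0])
        xy[:, 0] = np.clip(xy[:, 0], 0, mask.shape[1])
        xy[:, 1] = np.clip(xy[:, 1], 0, mask.shape[0])
        if rasterize_polygons([xy], *mask.shape).sum() >= min_area:
            polys.append(xy)
    return polys


def make_scene(spec: SceneSpec) -> GeneratedScene:
    """Render one scene and derive its aggregation-state annotations."""
    rng = np.random.default_rng(spec.seed)
    W, H = spec.image_size
    amin, amax = spec.blob_axes_range

    centers: list[tuple[float, float]] = []
    blob_masks: list[np.ndarray] = []
    heat = np.zeros((H, W), dtype=np.float64)
    for _ in range(spec.n_blobs):
        placed = False
        for _attempt in range(100):
            a = rng.uniform(amin, amax)
            b = rng.uniform(0.55 * a, 0.9 * a)
            if centers and rng.random() < spec.cluster_prob:
                bx, by = centers[rng.integers(len(centers))]
                cx = bx + rng.uniform(-1.4 * a, 1.4 * a)
                cy = by + rng.uniform(-1.4 * a, 1.4 * a)
            else:
                cx = rng.uniform(amax, W - amax)
                cy = rng.uniform(amax, H - amax)
            if not (a <= cx <= W - a and b <= cy <= H - b):
                continue
            theta = rng.uniform(0, np.pi)
            mask, hprof = _ellipse_mask_and_heat(W, H, cx, cy, a, b, theta)
            if not mask.any():
                continue
            peak = rng.uniform(*spec.blob_intensity_range)
            heat = np.maximum(heat, hprof * peak)
            centers.append((cx, cy))
            blob_masks.append(mask)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place blob within bounds after 100 attempts "
                f"(image {W}x{H}, axes up to {amax})")

    # cage bars: vertical dark occluders drawn over everything
    bars = np.zeros((H, W), dtype=bool)
    for _ in range(spec.occluder_bars):
        x0 = int(rng.integers(0, max(W - spec.occluder_width, 1)))
        bars[:, x0:x0 + spec.occluder_width] = True

    clean = np.maximum(spec.background_level, heat)
    clean[bars] = spec.occluder_level
    noisy = clean + rng.normal(0, spec.noise_sigma, clean.shape)
    image = np.clip(noisy, 0, 255).astype(np.uint8)

    # group blobs by touching (dilation-by-1 overlap), then label groups
    n = len(blob_masks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    dilated = [ndimage.binary_dilation(m) for m in blob_masks]
    for i in range(n):
        for j in range(i + 1, n):
            if (dilated[i] & blob_masks[j]).any():
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    instances: list[PolygonInstance] = []
    truth_masks: list[np.ndarray] = []
    members_out: list[list[int]] = []
    for members in groups.values():
        union = np.zeros((H, W), dtype=bool)
        for i in members:
            union |= blob_masks[i]
        visible = union & ~bars
        if not visible.any():
            continue
        if len(members) == 1:
            occluded_frac = 1.0 - visible.sum() / union.sum()
            category = ("chicken-half"
                        if occluded_frac > spec.occluded_fraction_threshold
                        else "chicken-whole")
        elif len(members) <= 3:
            category = "chicken-few"
        else:
            category = "chicken-many"
        polys = _trace_polygons(visible)
        if not polys:
            continue
        tmask = rasterize_polygons(polys, H, W)
        # one instance per contiguous visible region? No: the aggregation
        # region is annotated as ONE instance, possibly multi-polygon.
        inst = PolygonInstance(category, polys[0])
        inst.extra_polys = polys[1:]  # type: ignore[attr-defined]
        instances.append(inst)
        truth_masks.append(tmask)
        members_out.append(members)
    return GeneratedScene(image, instances, truth_masks, blob_masks,
                          members_out)


def instance_polygons(inst: PolygonInstance) -> list[np.ndarray]:
    return [inst.vertices] + list(getattr(inst, "extra_polys", []))


def make_video(spec: SceneSpec, n_frames: int,
               motion_frames: set[int] | frozenset[int],
               displacement: float = 18.0) -> FrameSequence:
    """A mostly static scene; at each motion frame the flock shifts by a
    fixed offset and stays, so only motion frames differ from their
    predecessor (above the noise floor)."""
    motion_frames = set(motion_frames)
    if motion_frames and (min(motion_frames) < 1
                          or max(motion_frames) >= n_frames):
        raise ValueError("motion frames must lie in [1, n_frames)")
    rng = np.random.default_rng(spec.seed + 7919)
    base = dataclasses.replace(spec, noise_sigma=0.0, occluder_bars=0)
    scene = make_scene(base)
    clean = scene.image.astype(np.float64)
    frames = []
    offset = 0
    for i in range(n_frames):
        if i in motion_frames:
            offset += int(displacement)
        shifted = np.zeros_like(clean)
        if offset < clean.shape[1]:
            shifted[:, offset:] = clean[:, :clean.shape[1] - offset]
        shifted[shifted < spec.background_level] = spec.background_level
        noisy = shifted + rng.normal(0, spec.noise_sigma, clean.shape)
        frames.append(GrayFrame(np.clip(noisy, 0, 255).astype(np.uint8), i))
    return FrameSequence(frames, fps=25.0)


@dataclasses.dataclass
class DatasetDistribution:
    """Per-scene sampling ranges mimicking the real flock imbalance
    (whole > few > many > half)."""

    n_blobs_range: tuple[int, int] = (3, 9)
    cluster_prob_range: tuple[float, float] = (0.15, 0.55)
    occluder_bars_range: tuple[int, int] = (0, 5)
    image_size: tuple[int, int] = (512, 512)


def make_dataset(n_images: int, dist: DatasetDistribution | None = None,
                 seed: int = 0, out_dir: str | pathlib.Path | None = None
                 ) -> tuple[CocoDataset, dict[int, np.ndarray],
                            list[GeneratedScene]]:
    """Generate a COCO-valid dataset of synthetic scenes.

    Returns (dataset, image-id -> pixels, scenes).  With ``out_dir`` set,
    writes images/ PNGs and annotations.json (byte-deterministic for a
    fixed seed).
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    dist = dist or DatasetDistribution()
    rng = np.random.default_rng(seed)
    ds = CocoDataset()
    pixels: dict[int, np.ndarray] = {}
    scenes: list[GeneratedScene] = []
    ann_id = 1
    for img_id in range(1, n_images + 1):
        spec = SceneSpec(
            image_size=dist.image_size,
            n_blobs=int(rng.integers(dist.n_blobs_range[0],
                                     dist.n_blobs_range[1] + 1)),
            cluster_prob=float(rng.uniform(*dist.cluster_prob_range)),
            occluder_bars=int(rng.integers(dist.occluder_bars_range[0],
                                           dist.occluder_bars_range[1] + 1)),
            occluder_width=int(rng.integers(4, 10)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        scene = make_scene(spec)
        W, H = dist.image_size
        ds.images.append({
            "id": img_id,
            "file_name": f"scene_{img_id:06d}.png",
            "height": H,
            "width": W,
        })
        pixels[img_id] = scene.image
        scenes.append(scene)
        for inst in scene.instances:
            ds.annotations.append(annotation_from_polys(
                instance_polygons(inst), ann_id, img_id,
                CATEGORY_IDS[inst.category], H, W))
            ann_id += 1
    ds.validate()
    if out_dir is not None:
        out = pathlib.Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        for img_id, arr in pixels.items():
            Image.fromarray(arr).save(
                out / "images" / f"scene_{img_id:06d}.png",
                format="PNG", compress_level=6)
        ds.save(out / "annotations.json")
    return ds, pixels, scenes


def make_easy_dataset(n_images: int, seed: int = 0, size: int = 256
                      ) -> tuple[CocoDataset, dict[int, np.ndarray],
                                 list[GeneratedScene]]:
    """One large, bright, unoccluded bird per scene: the easiest setting
    the generator produces, used for micro-training sanity runs."""
    rng = np.random.default_rng(seed)
    ds = CocoDataset()
    pixels: dict[int, np.ndarray] = {}
    scenes = []
    ann_id = 1
    for img_id in range(1, n_images + 1):
        spec = SceneSpec(
            image_size=(size, size),
            n_blobs=1,
            blob_intensity_range=(200, 245),
            blob_axes_range=(30.0, 48.0),
            background_level=40.0,
            noise_sigma=2.0,
            occluder_bars=0,
            cluster_prob=0.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        scene = make_scene(spec)
        ds.images.append({"id": img_id,
                          "file_name": f"easy_{img_id:06d}.png",
                          "height": size, "width": size})
        pixels[img_id] = scene.image
        scenes.append(scene)
        for inst in scene.instances:
            ds.annotations.append(annotation_from_polys(
                instance_polygons(inst), ann_id, img_id,
                CATEGORY_IDS[inst.category], size, size))
            ann_id += 1
    return ds.validate(), pixels, scenes
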