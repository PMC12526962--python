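"""Keyframe extraction from thermal video by inter-frame differencing.

Thermal footage of caged birds is highly redundant: at 25 fps adjacent
frames are near-identical unless the flock moves.  A frame is kept as a
keyframe when the mean absolute grayscale difference against its
predecessor exceeds a threshold ``T`` (0–255 scale).  Selected frames are
resized (bilinear) to a square training resolution and stored as PNG.
"""

from __future__ import annotations

import dataclasses
import pathlib
from typing import Sequence

import numpy as np
from PIL import Image

_BT601 = np.array([0.299, 0.587, 0.114])

IMAGE_EXTENSIONS = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}


@dataclasses.dataclass
class GrayFrame:
    """A single grayscale frame: uint8 intensities plus its ordinal index."""

    pixels: np.ndarray
    index: int

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("GrayFrame expects a 2-D intensity grid")
        if self.pixels.size == 0:
            raise ValueError("empty frame")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclasses.dataclass
class FrameSequence:
    frames: list[GrayFrame]
    fps: float = 25.0

    def __post_init__(self):
        idx = [f.index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be strictly increasing")
        shapes = {f.pixels.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError("all frames must share dimensions")

    def __len__(self) -> int:
        return len(self.frames)


@dataclasses.dataclass
class KeyframeConfig:
    """threshold_T: mean-difference threshold on the 0-255 grayscale.

    min_gap adds a minimum spacing between selected keyframes to suppress
    bursts of near-duplicates; 0 keeps the plain inter-frame rule.
    """

    threshold_T: float = 5.0
    min_gap: int = 0
    output_size: tuple[int, int] = (512, 512)

    def __post_init__(self):
        if self.threshold_T < 0:
            raise ValueError("threshold_T must be >= 0")
        if self.min_gap < 0:
            raise ValueError("min_gap must be >= 0")
        if min(self.output_size) <= 0:
            raise ValueError("output_size components must be positive")


def to_grayscale(frame: np.ndarray, index: int = 0) -> GrayFrame:
    """ITU-R BT.601 luma conversion of an RGB frame, rounded to uint8."""
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return GrayFrame(frame.astype(np.uint8), index)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError(f"expected HxWx3 RGB input, got shape {frame.shape}")
    gray = np.rint(frame.astype(np.float64) @ _BT601)
    return GrayFrame(np.clip(gray, 0, 255).astype(np.uint8), index)


def mean_abs_difference(f1: GrayFrame, f2: GrayFrame) -> float:
    """Mean absolute intensity difference between two frames."""
    if f1.pixels.shape != f2.pixels.shape:
        raise ValueError(
            f"frame shape mismatch: {f1.pixels.shape} vs {f2.pixels.shape}")
    d = np.abs(f1.pixels.astype(np.int16) - f2.pixels.astype(np.int16))
    return float(d.mean())


def extract_keyframes(seq: FrameSequence, cfg: KeyframeConfig) -> list[int]:
    """Indices i >= 1 whose mean difference to frame i-1 exceeds the
    threshold, honouring the minimum keyframe spacing.

    Deterministic; raising the threshold can only shrink the selection.
    """
    if len(seq) < 2:
        raise ValueError("keyframe extraction needs at least two frames")
    selected: list[int] = []
    last = None
    for prev, cur in zip(seq.frames, seq.frames[1:]):
        if mean_abs_difference(cur, prev) <= cfg.threshold_T:
            continue
        if last is not None and cur.index - last < cfg.min_gap:
            continue
        selected.append(cur.index)
        last = cur.index
    return selected


def resize_and_export(frames: Sequence[GrayFrame | np.ndarray],
                      cfg: KeyframeConfig,
                      out_dir: str | pathlib.Path) -> int:
    """Bilinear-resize frames to ``cfg.output_size`` and write PNGs.

    Returns the number of files written.  Fixed encoder settings make
    re-runs byte-identical.
    """
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = 0
    for i, frame in enumerate(frames):
        if isinstance(frame, GrayFrame):
            arr, idx = frame.pixels, frame.index
        else:
            arr, idx = np.asarray(frame), i
        img = Image.fromarray(arr.astype(np.uint8))
        img = img.resize(cfg.output_size, Image.BILINEAR)
        img.save(out / f"keyframe_{idx:06d}.png", format="PNG",
                 compress_level=6)
        n += 1
    return n


def load_frame_dir(path: str | pathlib.Path, fps: float = 25.0,
                   grayscale: bool = True) -> FrameSequence:
    """Load an ordered directory of image frames as a FrameSequence."""
    p = pathlib.Path(path)
    files = sorted(f for f in p.iterdir()
                   if f.suffix.lower() in IMAGE_EXTENSIONS)
    if not files:
        raise FileNotFoundError(f"no image frames found under {p}")
    frames = []
    for i, f in enumerate(files):
        arr = np.asarray(Image.open(f).convert("RGB"))
        frames.append(to_grayscale(arr, i) if grayscale
                      else GrayFrame(arr, i))
    return FrameSequence(frames, fps=fps)


def load_video(path: str | pathlib.Path, fps: float = 25.0) -> FrameSequence:
    """Load frames from a directory, or from a video container when a
    decoder is available (imageio); otherwise instructs to pre-extract."""
    p = pathlib.Path(path)
    if p.is_dir():
        return load_frame_dir(p, fps=fps)
    try:
        import imageio.v3 as iio
        frames = [to_grayscale(np.asarray(fr)[..., :3], i)
                  for i, fr in enumerate(iio.imiter(p))]
    except Exception as exc:  # decoder plugins are an optional runtime extra
        raise RuntimeError(
            f"cannot decode {p.name}: no video decoder available in this "
            "runtime; extract frames to a PNG directory first") from exc
    if not frames:
        raise ValueError(f"no frames decoded from {p}")
    return FrameSequence(frames, fps=fps)
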