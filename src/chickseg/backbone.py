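"""ResNet feature extractor with per-bottleneck CBAM refinement.

ResNet-v1 bottlenecks (1x1 -> 3x3 -> 1x1, stride on the 3x3) with group
normalisation, four stages producing C2-C5 at strides 4/8/16/32 and —
at unit width — channel widths 256/512/1024/2048.  When enabled, a CBAM
block refines every bottleneck's output; by default it is applied after
the residual addition ("post_residual"), with "pre_residual" (refine the
branch before the skip-add) available as the conventional alternative.

A width multiplier scales all channel counts, allowing the same
architecture to run at desk scale; the CBAM reduction ratio is clipped
per block to the largest divisor of the channel count not exceeding the
configured value.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .attention import CBAM
from .nn import Tensor

STAGE_BLOCKS = {50: (3, 4, 6, 3), 101: (3, 4, 23, 3)}
BASE_PLANES = (64, 128, 256, 512)
EXPANSION = 4


@dataclasses.dataclass
class BackboneConfig:
    depth: int = 101
    cbam_enabled: bool = True
    reduction_r: int = 16
    cbam_placement: str = "post_residual"   # or "pre_residual"
    width_mult: float = 1.0
    mlp_bias: bool = False
    pretrained: str | None = None           # optional weight archive path
    seed: int = 0

    def __post_init__(self):
        if self.depth not in STAGE_BLOCKS:
            raise ValueError(f"depth must be one of {set(STAGE_BLOCKS)}")
        if self.cbam_placement not in ("post_residual", "pre_residual"):
            raise ValueError("cbam_placement must be post_residual or "
                             "pre_residual")

    def scaled_planes(self) -> list[int]:
        return [max(4, int(round(p * self.width_mult))) for p in BASE_PLANES]


def _effective_reduction(channels: int, requested: int) -> int:
    r = min(requested, channels)
    while channels % r:
        r -= 1
    return max(r, 1)


class Bottleneck(nn.Module):
    def __init__(self, cin: int, planes: int, stride: int,
                 cfg: BackboneConfig, rng: np.random.Generator):
        cout = planes * EXPANSION
        self.conv1 = nn.Conv2d(cin, planes, 1, rng, bias=False)
        self.norm1 = nn.GroupNorm(planes)
        self.conv2 = nn.Conv2d(planes, planes, 3, rng, stride=stride,
                               padding=1, bias=False)
        self.norm2 = nn.GroupNorm(planes)
        self.conv3 = nn.Conv2d(planes, cout, 1, rng, bias=False)
        self.norm3 = nn.GroupNorm(cout)
        if stride != 1 or cin != cout:
            self.down_conv = nn.Conv2d(cin, cout, 1, rng, stride=stride,
                                       bias=False)
            self.down_norm = nn.GroupNorm(cout)
        else:
            self.down_conv = None
            self.down_norm = None
        self.placement = cfg.cbam_placement
        if cfg.cbam_enabled:
            r = _effective_reduction(cout, cfg.reduction_r)
            self.cbam = CBAM(cout, r, rng, mlp_bias=cfg.mlp_bias)
        else:
            self.cbam = None

    def forward(self, x: Tensor) -> Tensor:
        out = nn.relu(self.norm1(self.conv1(x)))
        out = nn.relu(self.norm2(self.conv2(out)))
        out = self.norm3(self.conv3(out))
        identity = x if self.down_conv is None \
            else self.down_norm(self.down_conv(x))
        if self.cbam is not None and self.placement == "pre_residual":
            out = self.cbam(out)
        out = nn.relu(out + identity)
        if self.cbam is not None and self.placement == "post_residual":
            out = self.cbam(out)
        return out


class ResNetBackbone(nn.Module):
    def __init__(self, cfg: BackboneConfig | None = None,
                 rng: np.random.Generator | None = None):
        self.cfg = cfg = cfg or BackboneConfig()
        rng = rng or np.random.default_rng(cfg.seed)
        planes = cfg.scaled_planes()
        stem_ch = planes[0]
        self.stem_conv = nn.Conv2d(3, stem_ch, 7, rng, stride=2, padding=3,
                                   bias=False)
        self.stem_norm = nn.GroupNorm(stem_ch)
        self.stages = []
        cin = stem_ch
        for si, (p, nblocks) in enumerate(zip(planes,
                                              STAGE_BLOCKS[cfg.depth])):
            blocks = []
            for bi in range(nblocks):
                stride = 2 if (bi == 0 and si > 0) else 1
                blocks.append(Bottleneck(cin, p, stride, cfg, rng))
                cin = p * EXPANSION
            self.stages.append(blocks)
        self.out_channels = [p * EXPANSION for p in planes]

    def forward(self, x: Tensor) -> dict[str, Tensor]:
        h, w = x.shape[2], x.shape[3]
        if h % 32 or w % 32:
            raise ValueError(
                f"input spatial size {h}x{w} must be divisible by 32")
        out = nn.relu(self.stem_norm(self.stem_conv(x)))
        out = nn.max_pool2d(out, 3, 2, 1)
        feats = {}
        for si, blocks in enumerate(self.stages):
            for blk in blocks:
                out = blk(out)
            feats[f"C{si + 2}"] = out
        return feats

    def attention_parameter_count(self) -> int:
        return sum(blk.cbam.attention_parameter_count()
                   for blocks in self.stages for blk in blocks
                   if blk.cbam is not None)


def backbone_forward(image: np.ndarray, cfg: BackboneConfig | None = None,
                     model: ResNetBackbone | None = None
                     ) -> dict[str, np.ndarray]:
    """Run a (3,H,W) image through the backbone; returns C2-C5 arrays."""
    if model is None:
        model = ResNetBackbone(cfg)
    img = np.asarray(image, dtype=np.float32)
    if img.ndim != 3 or img.shape[0] != 3:
        raise ValueError("expected a (3,H,W) image")
    with nn.no_grad():
        feats = model(Tensor(img[None]))
    return {k: v.data[0] for k, v in feats.items()}


def expected_cbam_parameter_count(cfg: BackboneConfig) -> int:
    """Closed-form count of the attention parameters CBAM adds."""
    total = 0
    planes = cfg.scaled_planes()
    for p, nblocks in zip(planes, STAGE_BLOCKS[cfg.depth]):
        cout = p * EXPANSION
        r = _effective_reduction(cout, cfg.reduction_r)
        hidden = cout // r
        per_block = 2 * cout * hidden + 2 * 7 * 7 + 1
        if cfg.mlp_bias:
            per_block += hidden + cout
        total += nblocks * per_block
    return total
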