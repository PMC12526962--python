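"""Feature pyramid necks: plain FPN and the attention-guided AC-FPN.

AC-FPN augments the top of the pyramid with two modules before the
top-down pathway:

* CEM (context extraction): a densely connected ladder of dilated 3x3
  convolutions (rates 3, 6, 12, 18, 24 by default) over the deepest
  backbone map C5, each block consuming C5 concatenated with all earlier
  block outputs, fused with a projected coarse path by a 1x1 convolution.
  Deformable sampling is used when the runtime provides a kernel for it;
  otherwise the blocks downgrade to plain dilated convolution (logged).
* AM (attention guidance): CxAM, spatial self-attention over the CEM
  output (queries/keys projected to a latent space, row-stochastic
  affinity over positions), followed by CnAM, which derives the affinity
  from C5 instead and applies it to the CEM features — correcting the
  positional drift the context blocks can introduce.

The attended map is fused with the C5 lateral connection and propagated
down the usual FPN top-down path; every emitted level P2-P5 has the same
channel width, with an optional stride-2 P6 for proposals only.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from . import nn
from .nn import Tensor

logger = logging.getLogger(__name__)

_DEFORMABLE_AVAILABLE = False   # no deformable sampling kernel in-runtime


@dataclasses.dataclass
class CEMConfig:
    dilations: tuple[int, ...] = (3, 6, 12, 18, 24)
    inner_channels: int = 256
    use_deformable: bool = True
    dense_connections: bool = True
    coarse_mode: str = "project"        # or "up2x_down2x"

    def __post_init__(self):
        if not self.dilations:
            raise ValueError("dilation list must be non-empty")
        if any(d <= 0 for d in self.dilations) or \
                list(self.dilations) != sorted(set(self.dilations)):
            raise ValueError("dilations must be strictly increasing and "
                             "positive")


@dataclasses.dataclass
class NeckConfig:
    type: str = "acfpn"                 # 'fpn' | 'acfpn'
    out_channels: int = 256
    latent_channels: int = 64           # CxAM/CnAM latent width
    cem: CEMConfig = dataclasses.field(default_factory=CEMConfig)
    add_p6: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.type not in ("fpn", "acfpn"):
            raise ValueError("neck type must be 'fpn' or 'acfpn'")
        if self.latent_channels <= 0:
            raise ValueError("latent_channels must be positive")


class CEM(nn.Module):
    """Densely connected dilated-convolution context extractor."""

    def __init__(self, cin: int, cfg: CEMConfig, rng: np.random.Generator):
        self.cfg = cfg
        inner = cfg.inner_channels
        if cfg.use_deformable and not _DEFORMABLE_AVAILABLE:
            logger.warning("deformable convolution unavailable; CEM falls "
                           "back to plain dilated convolution")
        self.blocks = []
        ch_in = cin
        for d in cfg.dilations:
            self.blocks.append(nn.ConvNormRelu(ch_in, inner, 3, rng,
                                               padding=d, dilation=d))
            if cfg.dense_connections:
                ch_in = ch_in + inner
            else:
                ch_in = inner
        self.coarse = nn.Conv2d(cin, inner, 1, rng)
        n_cat = len(cfg.dilations) * inner + inner
        self.fuse = nn.Conv2d(n_cat, inner, 1, rng)

    def forward(self, f5: Tensor) -> Tensor:
        outs = []
        cur = f5
        for blk in self.blocks:
            y = blk(cur)
            outs.append(y)
            if self.cfg.dense_connections:
                cur = nn.concat([cur, y], axis=1)
            else:
                cur = y
        if self.cfg.coarse_mode == "up2x_down2x":
            up = nn.upsample_nearest2x(f5)
            coarse = nn.max_pool2d(self.coarse(up), 2, 2)
        else:
            coarse = self.coarse(f5)
        return self.fuse(nn.concat(outs + [coarse], axis=1))


def _spatial_self_attention(values: Tensor, q: Tensor, k: Tensor) -> Tensor:
    """Row-stochastic position affinity from (q, k), applied to values.

    q, k: (N, L, H, W); values: (N, C, H, W).  Affinity rows are softmax
    over all H*W positions of Q^T K scaled by 1/sqrt(L).
    """
    n, c = values.shape[0], values.shape[1]
    latent = q.shape[1]
    h, w = values.shape[2], values.shape[3]
    hw = h * w
    outs = []
    scale = 1.0 / math.sqrt(latent)
    for i in range(n):
        qi = nn.reshape(q, (n, latent, hw))
        ki = nn.reshape(k, (n, latent, hw))
        vi = nn.reshape(values, (n, c, hw))
        qf = nn.transpose(_index0(qi, i), (1, 0))          # (HW, L)
        kf = _index0(ki, i)                                # (L, HW)
        aff = nn.softmax(nn.matmul(qf, kf) * scale, axis=1)  # rows sum to 1
        vf = _index0(vi, i)                                # (C, HW)
        att = nn.matmul(vf, nn.transpose(aff, (1, 0)))     # (C, HW)
        outs.append(nn.reshape(att, (1, c, h, w)))
    return outs[0] if n == 1 else nn.concat(outs, axis=0)


def _index0(t: Tensor, i: int) -> Tensor:
    """Select t[i] along axis 0 (keeps autodiff wiring via reshape)."""
    n = t.shape[0]
    if n == 1:
        return nn.reshape(t, t.shape[1:])
    # concat-based backward: use a slice of the data with scatter gradient
    data = t.data[i]

    def bw(g):
        full = np.zeros_like(t.data)
        full[i] = g
        t._accumulate(full)

    from .nn.tensor import _node
    return _node(data, (t,), bw)


class CxAM(nn.Module):
    """Contextual attention: self-affinity of the CEM output."""

    def __init__(self, channels: int, latent: int, rng: np.random.Generator):
        self.wq = nn.Conv2d(channels, latent, 1, rng, bias=False)
        self.wk = nn.Conv2d(channels, latent, 1, rng, bias=False)
        self.wv = nn.Conv2d(channels, channels, 1, rng, bias=False)

    def forward(self, f: Tensor) -> Tensor:
        att = _spatial_self_attention(self.wv(f), self.wq(f), self.wk(f))
        return f + att


class CnAM(nn.Module):
    """Content attention: affinity derived from the backbone's C5 map."""

    def __init__(self, f5_channels: int, channels: int, latent: int,
                 rng: np.random.Generator):
        self.wp = nn.Conv2d(f5_channels, latent, 1, rng, bias=False)
        self.wz = nn.Conv2d(f5_channels, latent, 1, rng, bias=False)

    def forward(self, f: Tensor, f5: Tensor) -> Tensor:
        if f.shape[2:] != f5.shape[2:]:
            raise ValueError("CnAM expects spatially aligned F and F5")
        att = _spatial_self_attention(f, self.wp(f5), self.wz(f5))
        return f + att


class Pyramid(nn.Module):
    """FPN / AC-FPN over backbone levels C2-C5 -> P2-P5 (+P6)."""

    def __init__(self, in_channels: list[int],
                 cfg: NeckConfig | None = None,
                 rng: np.random.Generator | None = None):
        self.cfg = cfg = cfg or NeckConfig()
        rng = rng or np.random.default_rng(cfg.seed)
        oc = cfg.out_channels
        self.laterals = [nn.Conv2d(c, oc, 1, rng) for c in in_channels]
        self.smooth = [nn.Conv2d(oc, oc, 3, rng, padding=1)
                       for _ in in_channels]
        if cfg.type == "acfpn":
            cem_cfg = dataclasses.replace(cfg.cem, inner_channels=oc)
            self.cem = CEM(in_channels[-1], cem_cfg, rng)
            self.cxam = CxAM(oc, cfg.latent_channels, rng)
            self.cnam = CnAM(in_channels[-1], oc, cfg.latent_channels, rng)
        else:
            self.cem = self.cxam = self.cnam = None

    def forward(self, feats: dict[str, Tensor]) -> dict[str, Tensor]:
        names = ["C2", "C3", "C4", "C5"]
        cs = [feats[n] for n in names]
        top = self.laterals[-1](cs[-1])
        if self.cem is not None:
            am = self.cnam(self.cxam(self.cem(cs[-1])), cs[-1])
            top = top + am
        outs = [top]
        for lateral, c in zip(self.laterals[-2::-1], cs[-2::-1]):
            top = lateral(c) + nn.upsample_nearest2x(top)
            outs.append(top)
        outs = outs[::-1]                      # P2..P5 pre-smoothing
        pyramid = {f"P{i + 2}": s(o)
                   for i, (s, o) in enumerate(zip(self.smooth, outs))}
        if self.cfg.add_p6:
            pyramid["P6"] = nn.max_pool2d(pyramid["P5"], 1, 2)
        return pyramid


def cem(F5: np.ndarray, cfg: CEMConfig | None = None,
        seed: int = 0) -> np.ndarray:
    """Functional CEM on a single (C,H,W) map (randomly initialised)."""
    cfg = cfg or CEMConfig()
    F5 = np.asarray(F5, dtype=np.float32)
    mod = CEM(F5.shape[0], cfg, np.random.default_rng(seed))
    with nn.no_grad():
        out = mod(Tensor(F5[None]))
    return out.data[0]


def cxam(F: np.ndarray, wq: np.ndarray, wk: np.ndarray,
         wv: np.ndarray) -> np.ndarray:
    """Functional CxAM on a (C,H,W) map with explicit 1x1 projections."""
    F = np.asarray(F, dtype=np.float32)
    mod = CxAM.__new__(CxAM)
    mod.wq = _conv_from(wq)
    mod.wk = _conv_from(wk)
    mod.wv = _conv_from(wv)
    with nn.no_grad():
        return mod(Tensor(F[None])).data[0]


def cnam(F: np.ndarray, F5: np.ndarray, wp: np.ndarray,
         wz: np.ndarray) -> np.ndarray:
    """Functional CnAM: affinity from F5 applied to F, residual added."""
    F = np.asarray(F, dtype=np.float32)
    F5 = np.asarray(F5, dtype=np.float32)
    mod = CnAM.__new__(CnAM)
    mod.wp = _conv_from(wp)
    mod.wz = _conv_from(wz)
    with nn.no_grad():
        return mod(Tensor(F[None]), Tensor(F5[None])).data[0]


def _conv_from(w: np.ndarray) -> nn.Conv2d:
    w = np.asarray(w, dtype=np.float32)
    if w.ndim == 2:                         # (out, in) -> 1x1 conv
        w = w[:, :, None, None]
    mod = nn.Conv2d.__new__(nn.Conv2d)
    mod.stride, mod.padding, mod.dilation = 1, 0, 1
    mod.weight = Tensor(w, requires_grad=True)
    mod.bias = None
    return mod


def build_pyramid(feats: dict[str, np.ndarray],
                  cfg: NeckConfig | None = None,
                  model: Pyramid | None = None) -> dict[str, np.ndarray]:
    """Numpy-facing pyramid builder over C2-C5 arrays."""
    cfg = cfg or NeckConfig()
    sizes = [feats[f"C{i}"].shape[1:] for i in range(2, 6)]
    for (h1, w1), (h2, w2) in zip(sizes, sizes[1:]):
        if h1 != 2 * h2 or w1 != 2 * w2:
            raise ValueError("backbone levels must halve in spatial size")
    if model is None:
        model = Pyramid([feats[f"C{i}"].shape[0] for i in range(2, 6)], cfg)
    with nn.no_grad():
        out = model({k: Tensor(v[None]) for k, v in feats.items()})
    return {k: v.data[0] for k, v in out.items()}
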