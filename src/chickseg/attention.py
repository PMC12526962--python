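"""Convolutional block attention: channel attention then spatial attention.

Channel attention squeezes the feature map with global average and max
pooling, passes both descriptors through one shared two-layer MLP
(hidden width C/r, rectifier in between, no biases) and squashes the sum
with a sigmoid:

    Mc(F) = sigmoid(MLP(AvgPool(F)) + MLP(MaxPool(F)))

Spatial attention stacks the channel-axis mean and max planes and maps
them through a 7x7 convolution (padding 3):

    Ms(F) = sigmoid(f7x7([AvgPool(F); MaxPool(F)]))

The refinement is sequential: F' = Mc(F) * F, F'' = Ms(F') * F'.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .nn import Tensor


@dataclasses.dataclass
class ChannelAttentionParams:
    """Shared-MLP weights: w1 is (C/r, C), w2 is (C, C/r)."""

    mlp_w1: np.ndarray
    mlp_w2: np.ndarray

    def __post_init__(self):
        self.mlp_w1 = np.asarray(self.mlp_w1, dtype=np.float32)
        self.mlp_w2 = np.asarray(self.mlp_w2, dtype=np.float32)
        hidden, c = self.mlp_w1.shape
        if self.mlp_w2.shape != (c, hidden):
            raise ValueError("mlp_w2 must be (C, C/r) for mlp_w1 (C/r, C)")

    @classmethod
    def create(cls, channels: int, reduction_r: int,
               rng: np.random.Generator) -> "ChannelAttentionParams":
        if channels % reduction_r:
            raise ValueError(
                f"reduction ratio {reduction_r} does not divide "
                f"channel count {channels}")
        hidden = channels // reduction_r
        w1 = nn.kaiming_normal(rng, (hidden, channels), channels)
        w2 = nn.kaiming_normal(rng, (channels, hidden), hidden)
        return cls(w1, w2)


@dataclasses.dataclass
class SpatialAttentionParams:
    """7x7 convolution over the 2-plane (avg, max) stack."""

    kernel: np.ndarray          # (1, 2, 7, 7)
    bias: np.ndarray | None = None
    padding: int = 3

    def __post_init__(self):
        self.kernel = np.asarray(self.kernel, dtype=np.float32)
        if self.kernel.shape != (1, 2, 7, 7):
            raise ValueError("spatial attention kernel must be (1, 2, 7, 7)")
        if self.bias is not None:
            self.bias = np.asarray(self.bias, dtype=np.float32)

    @classmethod
    def create(cls, rng: np.random.Generator) -> "SpatialAttentionParams":
        k = nn.kaiming_normal(rng, (1, 2, 7, 7), 2 * 49)
        return cls(k, np.zeros(1, np.float32))


def _mlp(v: Tensor, w1: Tensor, w2: Tensor) -> Tensor:
    return nn.matmul(nn.relu(nn.matmul(v, nn.transpose(w1, (1, 0)))),
                     nn.transpose(w2, (1, 0)))


def channel_attention_t(F: Tensor, w1: Tensor, w2: Tensor) -> Tensor:
    """Batched channel weights: F (N,C,H,W) -> (N,C)."""
    avg = F.mean(axis=(2, 3))
    mx = nn.tmax(nn.tmax(F, axis=3), axis=2)
    return nn.sigmoid(_mlp(avg, w1, w2) + _mlp(mx, w1, w2))


def spatial_attention_t(F: Tensor, kernel: Tensor,
                        bias: Tensor | None, padding: int = 3) -> Tensor:
    """Batched spatial weights: F (N,C,H,W) -> (N,1,H,W)."""
    avg = F.mean(axis=1, keepdims=True)
    mx = nn.tmax(F, axis=1, keepdims=True)
    stack = nn.concat([avg, mx], axis=1)
    return nn.sigmoid(nn.conv2d(stack, kernel, bias, padding=padding))


def channel_attention(F: np.ndarray,
                      params: ChannelAttentionParams) -> np.ndarray:
    """Channel weights of a single (C,H,W) feature map; each in (0,1)."""
    F = np.asarray(F, dtype=np.float32)
    if F.ndim != 3:
        raise ValueError("expected a (C,H,W) feature map")
    if params.mlp_w1.shape[1] != F.shape[0]:
        raise ValueError("params not dimensioned for this channel count")
    with nn.no_grad():
        out = channel_attention_t(Tensor(F[None]), Tensor(params.mlp_w1),
                                  Tensor(params.mlp_w2))
    return out.data[0]


def spatial_attention(F: np.ndarray,
                      params: SpatialAttentionParams) -> np.ndarray:
    """Spatial weight map of a single (C,H,W) feature map: (H,W) in (0,1)."""
    F = np.asarray(F, dtype=np.float32)
    if F.ndim != 3:
        raise ValueError("expected a (C,H,W) feature map")
    with nn.no_grad():
        out = spatial_attention_t(
            Tensor(F[None]), Tensor(params.kernel),
            None if params.bias is None else Tensor(params.bias),
            params.padding)
    return out.data[0, 0]


def cbam_refine(F: np.ndarray, cp: ChannelAttentionParams,
                sp: SpatialAttentionParams) -> np.ndarray:
    """Sequential channel-then-spatial refinement of a (C,H,W) map."""
    F = np.asarray(F, dtype=np.float32)
    mc = channel_attention(F, cp)
    f1 = F * mc[:, None, None]
    ms = spatial_attention(f1, sp)
    return f1 * ms[None, :, :]


class CBAM(nn.Module):
    """Trainable CBAM block operating on (N,C,H,W) tensors."""

    def __init__(self, channels: int, reduction_r: int,
                 rng: np.random.Generator, mlp_bias: bool = False):
        if channels % reduction_r:
            raise ValueError(
                f"reduction ratio {reduction_r} does not divide "
                f"channel count {channels}")
        cp = ChannelAttentionParams.create(channels, reduction_r, rng)
        sp = SpatialAttentionParams.create(rng)
        self.w1 = Tensor(cp.mlp_w1, requires_grad=True)
        self.w2 = Tensor(cp.mlp_w2, requires_grad=True)
        self.kernel = Tensor(sp.kernel, requires_grad=True)
        self.kbias = Tensor(sp.bias, requires_grad=True)
        if mlp_bias:
            hidden = channels // reduction_r
            self.b1 = Tensor(np.zeros(hidden, np.float32), requires_grad=True)
            self.b2 = Tensor(np.zeros(channels, np.float32),
                             requires_grad=True)
        else:
            self.b1 = self.b2 = None

    def _mlp(self, v: Tensor) -> Tensor:
        h = nn.matmul(v, nn.transpose(self.w1, (1, 0)))
        if self.b1 is not None:
            h = h + self.b1
        out = nn.matmul(nn.relu(h), nn.transpose(self.w2, (1, 0)))
        if self.b2 is not None:
            out = out + self.b2
        return out

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        avg = x.mean(axis=(2, 3))
        mx = nn.tmax(nn.tmax(x, axis=3), axis=2)
        mc = nn.sigmoid(self._mlp(avg) + self._mlp(mx))
        f1 = x * mc.reshape(n, c, 1, 1)
        ms = spatial_attention_t(f1, self.kernel, self.kbias)
        return f1 * ms

    def attention_parameter_count(self) -> int:
        n = self.w1.data.size + self.w2.data.size \
            + self.kernel.data.size + self.kbias.data.size
        if self.b1 is not None:
            n += self.b1.data.size + self.b2.data.size
        return int(n)
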