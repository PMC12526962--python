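"""Minimal reverse-mode automatic differentiation over numpy arrays.

The engine covers exactly the operations the detection stack needs:
broadcast arithmetic, matmul, 2-D (dilated/strided) convolution via im2col,
max pooling, nearest-neighbour upsampling, group normalisation, RoIAlign,
softmax and the detection losses.  Arrays are float32 throughout.  Graphs
are built eagerly; ``backward()`` runs a topological sweep.  A module-level
switch (`no_grad`) disables graph construction for inference.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _as_f32(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float32)
    return a


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._parents = tuple(parents) if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    # -- graph -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None):
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        self._accumulate(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar --------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient ``g`` down to ``shape`` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.reshape(shape)


def _node(data, parents, backward) -> Tensor:
    req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=parents,
                  backward=backward if req else None)


# -- elementwise / reshaping ---------------------------------------------

def add(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data + b.data

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out_data = a.data * b.data

    def bw(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), bw)


def reshape(a, shape) -> Tensor:
    a = _wrap(a)
    old = a.data.shape
    out = a.data.reshape(shape)

    def bw(g):
        a._accumulate(g.reshape(old))

    return _node(out, (a,), bw)


def transpose(a, axes) -> Tensor:
    a = _wrap(a)
    inv = np.argsort(axes)

    def bw(g):
        a._accumulate(g.transpose(inv))

    return _node(a.data.transpose(axes), (a,), bw)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [_wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in ts]
    out = np.concatenate([t.data for t in ts], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return _node(out, tuple(ts), bw)


def relu(a) -> Tensor:
    a = _wrap(a)
    mask = a.data > 0
    out = a.data * mask

    def bw(g):
        a._accumulate(g * mask)

    return _node(out, (a,), bw)


def sigmoid(a) -> Tensor:
    a = _wrap(a)
    s = 1.0 / (1.0 + np.exp(-np.clip(a.data, -60.0, 60.0)))

    def bw(g):
        a._accumulate(g * s * (1.0 - s))

    return _node(s, (a,), bw)


def exp(a) -> Tensor:
    a = _wrap(a)
    e = np.exp(a.data)

    def bw(g):
        a._accumulate(g * e)

    return _node(e, (a,), bw)


def log(a, eps: float = 1e-12) -> Tensor:
    a = _wrap(a)
    out = np.log(a.data + eps)

    def bw(g):
        a._accumulate(g / (a.data + eps))

    return _node(out, (a,), bw)


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        gg = np.asarray(g)
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        a._accumulate(np.broadcast_to(gg, a.data.shape).astype(np.float32))

    return _node(out, (a,), bw)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = _wrap(a)
    out = a.data.mean(axis=axis, keepdims=keepdims)
    denom = a.data.size / max(out.size, 1)

    def bw(g):
        gg = np.asarray(g) / denom
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        a._accumulate(np.broadcast_to(gg, a.data.shape).astype(np.float32))

    return _node(out, (a,), bw)


def tmax(a, axis, keepdims=False) -> Tensor:
    """Max along one axis; gradient flows to (first) argmax positions."""
    a = _wrap(a)
    out = a.data.max(axis=axis, keepdims=True)
    mask = (a.data == out)
    # split ties evenly so the gradient check stays clean
    mask = mask / mask.sum(axis=axis, keepdims=True)
    res = out if keepdims else np.squeeze(out, axis=axis)

    def bw(g):
        gg = np.asarray(g)
        if not keepdims:
            gg = np.expand_dims(gg, axis)
        a._accumulate((gg * mask).astype(np.float32))

    return _node(res, (a,), bw)


def matmul(a, b) -> Tensor:
    a, b = _wrap(a), _wrap(b)
    out = a.data @ b.data

    def bw(g):
        if a.requires_grad:
            ga = g @ np.swapaxes(b.data, -1, -2)
            a._accumulate(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.swapaxes(a.data, -1, -2) @ g
            b._accumulate(_unbroadcast(gb, b.data.shape))

    return _node(out, (a, b), bw)


def softmax(a, axis: int = -1) -> Tensor:
    a = _wrap(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        a._accumulate(s * (g - dot))

    return _node(s, (a,), bw)


# -- convolution ----------------------------------------------------------

_IM2COL_CACHE: dict[tuple, np.ndarray] = {}


def _im2col_indices(C, H, W, kh, kw, stride, padding, dilation):
    key = (C, H, W, kh, kw, stride, padding, dilation)
    idx = _IM2COL_CACHE.get(key)
    if idx is not None:
        return idx
    Hp, Wp = H + 2 * padding, W + 2 * padding
    oh = (Hp - dilation * (kh - 1) - 1) // stride + 1
    ow = (Wp - dilation * (kw - 1) - 1) // stride + 1
    c = np.repeat(np.arange(C), kh * kw)
    ky = np.tile(np.repeat(np.arange(kh), kw), C) * dilation
    kx = np.tile(np.tile(np.arange(kw), kh), C) * dilation
    oy = np.repeat(np.arange(oh), ow) * stride
    ox = np.tile(np.arange(ow), oh) * stride
    rows = (c[:, None] * Hp + ky[:, None] + oy[None, :]) * Wp \
        + kx[:, None] + ox[None, :]
    _IM2COL_CACHE[key] = rows
    if len(_IM2COL_CACHE) > 256:
        _IM2COL_CACHE.pop(next(iter(_IM2COL_CACHE)))
    return rows


def _conv_out_hw(H, W, kh, kw, stride, padding, dilation):
    oh = (H + 2 * padding - dilation * (kh - 1) - 1) // stride + 1
    ow = (W + 2 * padding - dilation * (kw - 1) - 1) // stride + 1
    return oh, ow


def conv2d(x, w, b=None, stride: int = 1, padding: int = 0,
           dilation: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout."""
    x, w = _wrap(x), _wrap(w)
    if b is not None:
        b = _wrap(b)
    N, C, H, W = x.data.shape
    Co, Ci, kh, kw = w.data.shape
    if Ci != C:
        raise ValueError(f"channel mismatch: input {C}, weight {Ci}")
    oh, ow = _conv_out_hw(H, W, kh, kw, stride, padding, dilation)
    if oh <= 0 or ow <= 0:
        raise ValueError("convolution output would be empty")
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding),
                             (padding, padding)))
    else:
        xp = x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    idx = _im2col_indices(C, H, W, kh, kw, stride, padding, dilation)
    cols = xp.reshape(N, -1)[:, idx]                     # (N, C*kh*kw, L)
    w2 = w.data.reshape(Co, -1)
    out = np.matmul(w2, cols).reshape(N, Co, oh, ow)
    if b is not None:
        out = out + b.data.reshape(1, Co, 1, 1)

    parents = (x, w) if b is None else (x, w, b)

    def bw(g):
        g2 = g.reshape(N, Co, -1)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            dw = np.einsum("ncl,nkl->ck", g2, cols, optimize=True)
            w._accumulate(dw.reshape(w.data.shape))
        if x.requires_grad:
            dcols = np.matmul(w2.T, g2)                  # (N, K, L)
            dxp = np.zeros((N, C * Hp * Wp), dtype=np.float32)
            flat_idx = idx.ravel()
            for n in range(N):
                np.add.at(dxp[n], flat_idx, dcols[n].ravel())
            dxp = dxp.reshape(N, C, Hp, Wp)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accumulate(dxp)

    return _node(out, parents, bw)


def max_pool2d(x, kernel: int = 2, stride: int | None = None,
               padding: int = 0) -> Tensor:
    x = _wrap(x)
    stride = stride or kernel
    N, C, H, W = x.data.shape
    oh, ow = _conv_out_hw(H, W, kernel, kernel, stride, padding, 1)
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding),
                             (padding, padding)),
                    constant_values=-np.inf)
    else:
        xp = x.data
    Hp, Wp = xp.shape[2], xp.shape[3]
    idx = _im2col_indices(1, H, W, kernel, kernel, stride, padding, 1)
    cols = xp.reshape(N * C, -1)[:, idx]                 # (N*C, k*k, L)
    arg = cols.argmax(axis=1)                            # (N*C, L)
    out = np.take_along_axis(cols, arg[:, None, :], axis=1)[:, 0, :]
    out = out.reshape(N, C, oh, ow)

    def bw(g):
        gf = g.reshape(N * C, -1)
        dxp = np.zeros((N * C, Hp * Wp), dtype=np.float32)
        src = np.take_along_axis(idx[None, :, :].repeat(N * C, axis=0),
                                 arg[:, None, :], axis=1)[:, 0, :]
        for n in range(N * C):
            np.add.at(dxp[n], src[n], gf[n])
        dxp = dxp.reshape(N, C, Hp, Wp)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        x._accumulate(dxp)

    return _node(out, (x,), bw)


def upsample_nearest2x(x) -> Tensor:
    x = _wrap(x)
    out = x.data.repeat(2, axis=-1).repeat(2, axis=-2)

    def bw(g):
        s = g.shape
        gg = g.reshape(*s[:-2], s[-2] // 2, 2, s[-1] // 2, 2)
        x._accumulate(gg.sum(axis=(-3, -1)))

    return _node(out, (x,), bw)


def group_norm(x, gamma, beta, groups: int, eps: float = 1e-5) -> Tensor:
    """GroupNorm over (C//G, H, W) per sample; affine per channel."""
    x, gamma, beta = _wrap(x), _wrap(gamma), _wrap(beta)
    N, C, H, W = x.data.shape
    if C % groups:
        raise ValueError("groups must divide channels")
    xg = x.data.reshape(N, groups, -1)
    mu = xg.mean(axis=2, keepdims=True)
    var = xg.var(axis=2, keepdims=True)
    istd = 1.0 / np.sqrt(var + eps)
    xhat = ((xg - mu) * istd).reshape(N, C, H, W)
    gam = gamma.data.reshape(1, C, 1, 1)
    out = xhat * gam + beta.data.reshape(1, C, 1, 1)

    def bw(g):
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxhat = (g * gam).reshape(N, groups, -1)
            xh = xhat.reshape(N, groups, -1)
            m = dxhat.shape[2]
            t1 = dxhat - dxhat.mean(axis=2, keepdims=True)
            t2 = xh * (dxhat * xh).sum(axis=2, keepdims=True) / m
            dx = istd * (t1 - t2)
            x._accumulate(dx.reshape(N, C, H, W).astype(np.float32))

    return _node(out, (x, gamma, beta), bw)


# -- RoIAlign -------------------------------------------------------------

def roi_align(feat, boxes: np.ndarray, output_size: int,
              spatial_scale: float, sampling_ratio: int = 2) -> Tensor:
    """Quantisation-free RoI pooling by regular-grid bilinear sampling.

    feat: Tensor (C, H, W); boxes: (R, 4) [x1,y1,x2,y2] in IMAGE coords.
    Returns (R, C, output_size, output_size).  Boxes carry no gradient.
    """
    feat = _wrap(feat)
    C, H, W = feat.data.shape
    boxes = np.asarray(boxes, dtype=np.float64) * spatial_scale
    R = boxes.shape[0]
    if R == 0:
        return Tensor(np.zeros((0, C, output_size, output_size), np.float32))
    if np.any(boxes[:, 2] <= boxes[:, 0]) or np.any(boxes[:, 3] <= boxes[:, 1]):
        raise ValueError("degenerate box passed to roi_align")
    sr = sampling_ratio
    P = output_size * sr
    bw_ = (boxes[:, 2] - boxes[:, 0]) / output_size     # bin sizes
    bh_ = (boxes[:, 3] - boxes[:, 1]) / output_size
    # sample point centres: per box a P x P grid
    gx = (np.arange(P) + 0.5) / sr                       # in bin units
    px = boxes[:, 0:1] + bw_[:, None] * gx[None, :]      # (R, P)
    py = boxes[:, 1:2] + bh_[:, None] * gx[None, :]
    # shift to pixel-centre convention
    px = px - 0.5
    py = py - 0.5
    x0 = np.floor(px).astype(np.int64)
    y0 = np.floor(py).astype(np.int64)
    lx = (px - x0).astype(np.float32)
    ly = (py - y0).astype(np.float32)
    x0c = np.clip(x0, 0, W - 1)
    x1c = np.clip(x0 + 1, 0, W - 1)
    y0c = np.clip(y0, 0, H - 1)
    y1c = np.clip(y0 + 1, 0, H - 1)
    # corner weights with out-of-bounds zeroing (points fully outside -> 0)
    inx = ((px >= -1.0) & (px <= W)).astype(np.float32)
    iny = ((py >= -1.0) & (py <= H)).astype(np.float32)
    fflat = feat.data.reshape(C, -1)

    # build (R,P,P) index/weight maps for the 4 corners
    def corners():
        for yy, wy in ((y0c, (1 - ly)), (y1c, ly)):
            for xx, wx in ((x0c, (1 - lx)), (x1c, lx)):
                iw = (yy[:, :, None] * W + xx[:, None, :])   # (R,P,P)
                ww = (wy * iny)[:, :, None] * (wx * inx)[:, None, :]
                yield iw.reshape(R, P * P), ww.reshape(R, P * P)

    corner_list = list(corners())
    samp = np.zeros((R, P * P, C), dtype=np.float32)
    for iw, ww in corner_list:
        samp += fflat.T[iw] * ww[:, :, None]
    samp = samp.reshape(R, P, P, C).transpose(0, 3, 1, 2)   # (R,C,P,P)
    out = samp.reshape(R, C, output_size, sr, output_size, sr)
    out = out.mean(axis=(3, 5))

    def bw(g):
        gg = (g / (sr * sr)).astype(np.float32)
        gup = gg.repeat(sr, axis=-1).repeat(sr, axis=-2)     # (R,C,P,P)
        gflat = gup.transpose(0, 2, 3, 1).reshape(R, P * P, C)
        dfeat = np.zeros((H * W, C), dtype=np.float32)
        for iw, ww in corner_list:
            np.add.at(dfeat, iw.ravel(),
                      (gflat * ww[:, :, None]).reshape(-1, C))
        feat._accumulate(dfeat.T.reshape(C, H, W))

    return _node(out, (feat,), bw)


# -- losses ---------------------------------------------------------------

def softmax_cross_entropy(logits, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy; logits (N, K), integer labels (N,)."""
    logits = _wrap(logits)
    labels = np.asarray(labels, dtype=np.int64)
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    loss = (lse - z[np.arange(n), labels]).mean()
    probs = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)

    def bw(g):
        d = probs.copy()
        d[np.arange(n), labels] -= 1.0
        logits._accumulate(np.float32(g) * d / n)

    return _node(np.float32(loss), (logits,), bw)


def bce_with_logits(logits, targets: np.ndarray,
                    normalizer: float | None = None) -> Tensor:
    """Binary cross-entropy on logits, summed then divided by normalizer
    (defaults to element count)."""
    logits = _wrap(logits)
    t = np.asarray(targets, dtype=np.float32)
    x = logits.data
    norm = float(normalizer) if normalizer is not None else x.size
    # stable: max(x,0) - x*t + log(1+exp(-|x|))
    loss = (np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))).sum() / norm
    s = 1.0 / (1.0 + np.exp(-x))

    def bw(g):
        logits._accumulate(np.float32(g) * (s - t) / norm)

    return _node(np.float32(loss), (logits,), bw)


def smooth_l1(pred, target: np.ndarray, beta: float = 1.0,
              normalizer: float | None = None) -> Tensor:
    pred = _wrap(pred)
    t = np.asarray(target, dtype=np.float32)
    d = pred.data - t
    ad = np.abs(d)
    norm = float(normalizer) if normalizer is not None else max(d.size, 1)
    elem = np.where(ad < beta, 0.5 * d * d / beta, ad - 0.5 * beta)
    loss = elem.sum() / norm

    def bw(g):
        gd = np.where(ad < beta, d / beta, np.sign(d))
        pred._accumulate(np.float32(g) * gd.astype(np.float32) / norm)

    return _node(np.float32(loss), (pred,), bw)
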