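"""Module system and standard layers on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor


def kaiming_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Module:
    """Lightweight container: parameters are discovered by attribute walk."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    out.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    walk(v)

        walk(self)
        return out

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}

        def walk(obj, prefix):
            if isinstance(obj, Module):
                for k, v in vars(obj).items():
                    walk(v, f"{prefix}{k}.")
            elif isinstance(obj, Tensor):
                state[prefix[:-1]] = obj.data
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    walk(v, f"{prefix}{i}.")
            elif isinstance(obj, dict):
                for k, v in obj.items():
                    walk(v, f"{prefix}{k}.")

        walk(self, "")
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = self.state_dict()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing keys in checkpoint: {sorted(missing)[:5]}")

        def walk(obj, prefix):
            if isinstance(obj, Module):
                for k, v in vars(obj).items():
                    walk(v, f"{prefix}{k}.")
            elif isinstance(obj, Tensor):
                key = prefix[:-1]
                arr = np.asarray(state[key], dtype=np.float32)
                if arr.shape != obj.data.shape:
                    raise ValueError(f"shape mismatch for {key}")
                obj.data = arr.copy()
            elif isinstance(obj, (list, tuple)):
                for i, v in enumerate(obj):
                    walk(v, f"{prefix}{i}.")
            elif isinstance(obj, dict):
                for k, v in obj.items():
                    walk(v, f"{prefix}{k}.")

        walk(self, "")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 bias: bool = True):
        self.stride, self.padding, self.dilation = stride, padding, dilation
        fan_in = cin * kernel * kernel
        self.weight = Tensor(
            kaiming_normal(rng, (cout, cin, kernel, kernel), fan_in),
            requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) \
            if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 bias: bool = True):
        self.weight = Tensor(kaiming_normal(rng, (cin, cout), cin),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) \
            if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = T.matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class GroupNorm(Module):
    def __init__(self, channels: int, groups: int | None = None,
                 eps: float = 1e-5):
        if groups is None:
            groups = 8
            while channels % groups:
                groups //= 2
        self.groups, self.eps = groups, eps
        self.gamma = Tensor(np.ones(channels, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return T.group_norm(x, self.gamma, self.beta, self.groups, self.eps)


class Sequential(Module):
    def __init__(self, *mods: Module):
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class ConvNormRelu(Module):
    """3x3/1x1 conv + GroupNorm + ReLU, the work-horse block of the heads."""

    def __init__(self, cin, cout, kernel, rng, stride=1, padding=0, dilation=1):
        self.conv = Conv2d(cin, cout, kernel, rng, stride=stride,
                           padding=padding, dilation=dilation, bias=False)
        self.norm = GroupNorm(cout)

    def forward(self, x: Tensor) -> Tensor:
        return T.relu(self.norm(self.conv(x)))


class SGD:
    """Stochastic gradient descent with momentum and weight decay."""

    def __init__(self, params: list[Tensor], lr: float, momentum: float = 0.9,
                 weight_decay: float = 1e-4, max_grad_norm: float | None = None):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.max_grad_norm = max_grad_norm
        self.velocity = [np.zeros_like(p.data) for p in params]

    def _clip(self):
        if self.max_grad_norm is None:
            return
        total = np.sqrt(sum(float((p.grad ** 2).sum())
                            for p in self.params if p.grad is not None))
        if total > self.max_grad_norm:
            scale = self.max_grad_norm / (total + 1e-12)
            for p in self.params:
                if p.grad is not None:
                    p.grad *= scale

    def step(self):
        self._clip()
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data -= self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
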