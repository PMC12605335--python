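"""Layer/module system: parameter registration, train/eval mode,
state-dict (de)serialisation, and the concrete layers the network uses."""

from __future__ import annotations

from typing import Iterator

import numpy as np

import contextlib

from . import functional as F
from .tensor import Parameter, Tensor

DTYPE = np.float32

_BN_STATS_FROZEN = False


@contextlib.contextmanager
def frozen_bn_stats():
    """Batch-norm layers keep using batch statistics but stop updating the
    running estimates.  Used for forward passes on augmented views, whose
    statistics should not contaminate the evaluation-mode estimates of the
    clean-data distribution."""
    global _BN_STATS_FROZEN
    prev = _BN_STATS_FROZEN
    _BN_STATS_FROZEN = True
    try:
        yield
    finally:
        _BN_STATS_FROZEN = prev


class Module:
    def __init__(self) -> None:
        self.training = True

    # -- registry -------------------------------------------------------------
    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield from val.named_modules(f"{prefix}{name}." if prefix else f"{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        sub = f"{prefix}{name}.{i}." if prefix else f"{name}.{i}."
                        yield from item.named_modules(sub)

    def named_parameters(self) -> Iterator[tuple[str, Parameter]]:
        for mprefix, mod in self.named_modules():
            for name, val in vars(mod).items():
                if isinstance(val, Parameter):
                    yield f"{mprefix}{name}", val

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self) -> Iterator[tuple[str, np.ndarray]]:
        for mprefix, mod in self.named_modules():
            for name in getattr(mod, "_buffers", ()):
                yield f"{mprefix}{name}", getattr(mod, name)

    def num_parameters(self) -> int:
        return sum(int(p.data.size) for p in self.parameters())

    # -- mode -----------------------------------------------------------------
    def train(self, mode: bool = True) -> "Module":
        for _, m in self.named_modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # -- (de)serialisation ----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = []
        for name, p in own.items():
            if name not in state:
                missing.append(name)
                continue
            p.data = np.asarray(state[name], dtype=p.data.dtype).reshape(p.data.shape)
        for mprefix, mod in self.named_modules():
            for bname in getattr(mod, "_buffers", ()):
                key = f"{mprefix}{bname}"
                if key in state:
                    setattr(mod, bname, np.asarray(state[key], dtype=DTYPE).reshape(getattr(mod, bname).shape))
                else:
                    missing.append(key)
        if missing:
            raise KeyError(f"state dict is missing entries: {missing[:5]}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.layers = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.silu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Conv2d(Module):
    """2-D convolution, Kaiming-normal init drawn from an explicit RNG so
    model construction is reproducible from a single seed."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, groups: int = 1, bias: bool = True):
        super().__init__()
        self.stride, self.padding, self.groups = stride, padding, groups
        fan_in = (cin // groups) * k * k
        std = float(np.sqrt(2.0 / fan_in))
        self.weight = Parameter(rng.normal(0.0, std, size=(cout, cin // groups, k, k)).astype(DTYPE))
        self.bias = Parameter(np.zeros(cout, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class Linear(Module):
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        bound = float(np.sqrt(1.0 / cin))
        self.weight = Parameter(rng.uniform(-bound, bound, size=(cin, cout)).astype(DTYPE))
        self.bias = Parameter(np.zeros(cout, dtype=DTYPE)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight  # matmul reports the MACs
        if self.bias is not None:
            out = out + self.bias
        return out


class BatchNorm2d(Module):
    """Batch-statistics normalisation over (B, H, W) per channel, with
    running statistics for evaluation mode."""

    _buffers = ("running_mean", "running_var")

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.weight = Parameter(np.ones(c, dtype=DTYPE))
        self.bias = Parameter(np.zeros(c, dtype=DTYPE))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            if not _BN_STATS_FROZEN:
                n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                self.running_mean = ((1 - self.momentum) * self.running_mean
                                     + self.momentum * mu).astype(DTYPE)
                self.running_var = ((1 - self.momentum) * self.running_var
                                    + self.momentum * var * (n / max(n - 1, 1))).astype(DTYPE)
        else:
            mu = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        return F.batch_norm(x, self.weight, self.bias, mu, var, self.eps,
                            batch_stats=self.training)


class LayerNorm(Module):
    """Normalisation over the last dimension (token embeddings)."""

    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(d, dtype=DTYPE))
        self.bias = Parameter(np.zeros(d, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return F.layer_norm(x, self.weight, self.bias, self.eps)


class ConvBNAct(Module):
    """Conv → batch norm → SiLU, the conv idiom used throughout."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, groups: int = 1, act: bool = True):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, rng, stride=stride, padding=k // 2,
                           groups=groups, bias=False)
        self.bn = BatchNorm2d(cout)
        self.act = SiLU() if act else Identity()

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.bn(self.conv(x)))
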