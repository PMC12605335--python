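"""Hybrid CNN-Transformer encoder.

The backbone follows the MobileViT recipe: a convolutional stem and
inverted-residual (MobileNetV2-style) stages for the high-resolution
levels, with shape-preserving MobileViT blocks — local convolution, then
patch-wise transformer attention (unfold → attend → fold), then
convolutional fusion — in the three deepest stages.  The encoder emits a
five-level feature pyramid at strides 2, 4, 8, 16 and 32.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import nn
from ..nn import Tensor
from ..nn import functional as F

STRIDES = (2, 4, 8, 16, 32)


@dataclass
class EncoderConfig:
    """Backbone hyper-parameters.

    ``small`` is the reference configuration (the standard small MobileViT
    channel plan); ``tiny-test`` is a drastically narrowed variant for fast
    CPU experiments.  ``stage_channels`` are the channel widths of the five
    pyramid levels.
    """

    variant: str = "small"
    stem_channels: int = 16
    stage_channels: tuple[int, ...] = (32, 64, 96, 128, 160)
    transformer_dims: tuple[int, ...] = (144, 192, 240)
    transformer_depths: tuple[int, ...] = (2, 4, 3)
    patch_size: int = 2
    expand_ratio: int = 4
    heads: int = 4
    width_multiplier: float = 1.0

    def __post_init__(self):
        if len(self.stage_channels) != 5:
            raise ValueError("stage_channels must list exactly 5 pyramid widths")
        if self.width_multiplier != 1.0:
            m = self.width_multiplier
            scale = lambda c: max(4, int(round(c * m / 4)) * 4)
            self.stem_channels = scale(self.stem_channels)
            self.stage_channels = tuple(scale(c) for c in self.stage_channels)
            self.transformer_dims = tuple(scale(d) for d in self.transformer_dims)
            self.width_multiplier = 1.0

    @classmethod
    def small(cls) -> "EncoderConfig":
        return cls()

    @classmethod
    def tiny_test(cls) -> "EncoderConfig":
        return cls(variant="tiny-test", stem_channels=8,
                   stage_channels=(8, 16, 24, 32, 40),
                   transformer_dims=(24, 32, 40),
                   transformer_depths=(1, 1, 1),
                   expand_ratio=2, heads=2)

    @classmethod
    def from_name(cls, name: str) -> "EncoderConfig":
        if name == "small":
            return cls.small()
        if name in ("tiny-test", "tiny_test", "tiny"):
            return cls.tiny_test()
        raise ValueError(f"unknown encoder variant {name!r}")


@dataclass
class FeaturePyramid:
    """The encoder's five intermediate feature maps."""

    levels: list
    strides: tuple[int, ...] = STRIDES
    channels: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if not self.channels:
            self.channels = tuple(l.shape[1] for l in self.levels)


class InvertedResidual(nn.Module):
    """MobileNetV2 block: 1x1 expand, 3x3 depthwise, 1x1 project, with a
    residual path when the shape is preserved."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 stride: int = 1, expand: int = 4):
        super().__init__()
        hid = cin * expand
        self.use_res = stride == 1 and cin == cout
        self.expand = nn.ConvBNAct(cin, hid, 1, rng)
        self.depthwise = nn.ConvBNAct(hid, hid, 3, rng, stride=stride, groups=hid)
        self.project = nn.ConvBNAct(hid, cout, 1, rng, act=False)

    def forward(self, x: Tensor) -> Tensor:
        out = self.project(self.depthwise(self.expand(x)))
        return out + x if self.use_res else out


class TransformerLayer(nn.Module):
    """Pre-norm transformer encoder layer (multi-head self-attention + MLP)."""

    def __init__(self, dim: int, mlp_dim: int, heads: int, rng: np.random.Generator):
        super().__init__()
        self.heads = heads
        self.norm1 = nn.LayerNorm(dim)
        self.qkv = nn.Linear(dim, 3 * dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        self.norm2 = nn.LayerNorm(dim)
        self.fc1 = nn.Linear(dim, mlp_dim, rng)
        self.fc2 = nn.Linear(mlp_dim, dim, rng)

    def _attention(self, x: Tensor) -> Tensor:
        b, n, d = x.shape
        h = self.heads
        dh = d // h
        qkv = self.qkv(x).reshape(b, n, 3, h, dh).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (b, h, n, dh)
        att = F.softmax(q @ k.transpose(0, 1, 3, 2) * (dh ** -0.5), axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(b, n, d)
        return self.proj(out)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self._attention(self.norm1(x))
        return x + self.fc2(self.fc1(self.norm2(x)).silu())


class _Transformer(nn.Module):
    def __init__(self, dim: int, mlp_dim: int, depth: int, heads: int, rng: np.random.Generator):
        super().__init__()
        self.layers = [TransformerLayer(dim, mlp_dim, heads, rng) for _ in range(depth)]
        self.norm = nn.LayerNorm(dim)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return self.norm(x)


class MobileViTBlock(nn.Module):
    """Shape-preserving hybrid block: local 3x3 convolution, unfold into
    non-overlapping patches, transformer over each patch-position sequence,
    fold back, and fuse with the input through concatenation + 3x3 conv."""

    def __init__(self, c: int, dim: int, depth: int, mlp_dim: int,
                 patch: int, heads: int, rng: np.random.Generator):
        super().__init__()
        self.patch = patch
        self.local = nn.ConvBNAct(c, c, 3, rng)
        self.to_tokens = nn.Conv2d(c, dim, 1, rng, bias=False)
        self.transformer = _Transformer(dim, mlp_dim, depth, heads, rng)
        self.from_tokens = nn.ConvBNAct(dim, c, 1, rng)
        self.fuse = nn.ConvBNAct(2 * c, c, 3, rng)

    def forward(self, x: Tensor) -> Tensor:
        b, c, hh, ww = x.shape
        p = self.patch
        y = self.to_tokens(self.local(x))
        d = y.shape[1]
        # odd spatial sizes: resize to the nearest patch multiple and back
        ph = int(np.ceil(hh / p)) * p
        pw = int(np.ceil(ww / p)) * p
        if (ph, pw) != (hh, ww):
            y = F.interpolate_bilinear(y, (ph, pw))
        nh, nw = ph // p, pw // p
        # unfold: (B, d, H, W) -> (B*p*p, nh*nw, d), one sequence per in-patch offset
        t = y.reshape(b, d, nh, p, nw, p).transpose(0, 3, 5, 2, 4, 1).reshape(b * p * p, nh * nw, d)
        t = self.transformer(t)
        y = t.reshape(b, p, p, nh, nw, d).transpose(0, 5, 3, 1, 4, 2).reshape(b, d, ph, pw)
        if (ph, pw) != (hh, ww):
            y = F.interpolate_bilinear(y, (hh, ww))
        y = self.from_tokens(y)
        return self.fuse(nn.concat([x, y], axis=1))


class MobileViTEncoder(nn.Module):
    """Five-stage encoder producing the feature pyramid at strides 2..32."""

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        ch = config.stage_channels
        dims = config.transformer_dims
        depths = config.transformer_depths
        e, p, h = config.expand_ratio, config.patch_size, config.heads
        self.stem = nn.ConvBNAct(3, config.stem_channels, 3, rng, stride=2)
        self.stage1 = InvertedResidual(config.stem_channels, ch[0], rng, stride=1, expand=e)
        self.stage2 = nn.Sequential(
            InvertedResidual(ch[0], ch[1], rng, stride=2, expand=e),
            InvertedResidual(ch[1], ch[1], rng, expand=e),
            InvertedResidual(ch[1], ch[1], rng, expand=e))
        self.stage3 = nn.Sequential(
            InvertedResidual(ch[1], ch[2], rng, stride=2, expand=e),
            MobileViTBlock(ch[2], dims[0], depths[0], 2 * dims[0], p, h, rng))
        self.stage4 = nn.Sequential(
            InvertedResidual(ch[2], ch[3], rng, stride=2, expand=e),
            MobileViTBlock(ch[3], dims[1], depths[1], 2 * dims[1], p, h, rng))
        self.stage5 = nn.Sequential(
            InvertedResidual(ch[3], ch[4], rng, stride=2, expand=e),
            MobileViTBlock(ch[4], dims[2], depths[2], 2 * dims[2], p, h, rng))

    def forward(self, x: Tensor) -> FeaturePyramid:
        _, _, hh, ww = x.shape
        if hh % 32 or ww % 32:
            raise ValueError(
                f"input spatial size {hh}x{ww} must be divisible by 32 "
                f"(five stride-2 stages)")
        l1 = self.stage1(self.stem(x))
        l2 = self.stage2(l1)
        l3 = self.stage3(l2)
        l4 = self.stage4(l3)
        l5 = self.stage5(l4)
        return FeaturePyramid(levels=[l1, l2, l3, l4, l5],
                              channels=tuple(self.config.stage_channels))
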