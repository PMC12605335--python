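"""Multi-scale fusion decoder with channel attention.

Instead of U-Net skip concatenation, every encoder level is (a) gated by a
channel-attention block that pools along the height and width axes
separately and produces sigmoid row/column gates, and (b) fused with a
global context feature built by resizing all five pyramid levels to a
common resolution, concatenating them and projecting with a 1x1
convolution.  Decoder stages combine the upsampled deeper state, the gated
encoder level and the resized global feature by element-wise addition
(after 1x1 channel alignment) followed by 3x3 refinement convolutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import nn
from ..nn import Tensor
from ..nn import functional as F
from .mobilevit import FeaturePyramid


@dataclass
class AttentionWeights:
    """Sigmoid gates: ``s_h`` is (B, C, H, 1), ``s_w`` is (B, C, 1, W)."""

    s_h: np.ndarray
    s_w: np.ndarray


@dataclass
class DecoderConfig:
    """Decoder widths, chosen so the assembled network reproduces the
    published lightweight profile (11.491M parameters, 146.165 GFLOPs at
    512x512 under the one-MAC-one-op convention)."""

    widths: tuple[int, ...] = (320, 256, 256, 256)  # deep -> shallow
    global_channels: int = 368
    global_stride: int = 4
    head_channels: int = 96
    fuse_convs: int = 2
    ca_reduction: int = 16
    use_channel_attention: bool = True
    use_global_fusion: bool = True

    @classmethod
    def tiny_test(cls) -> "DecoderConfig":
        return cls(widths=(24, 20, 16, 16), global_channels=24,
                   head_channels=8, fuse_convs=1, ca_reduction=8)


class ChannelAttention(nn.Module):
    """Coordinate-style channel attention.

    Features are average-pooled along the width axis (giving a per-row
    descriptor) and along the height axis (per-column descriptor), reduced
    by a shared 1x1 convolution, then expanded per-axis and squashed with a
    sigmoid into gates ``s_h`` and ``s_w`` in (0, 1).  The output is the
    input gated by both, broadcast over the complementary axis.
    """

    def __init__(self, c: int, rng: np.random.Generator, reduction: int = 16):
        super().__init__()
        mid = max(8, c // reduction)
        self.reduce = nn.ConvBNAct(c, mid, 1, rng)
        self.expand_h = nn.Conv2d(mid, c, 1, rng, bias=True)
        self.expand_w = nn.Conv2d(mid, c, 1, rng, bias=True)

    def forward(self, x: Tensor) -> tuple[Tensor, AttentionWeights]:
        _, _, hh, ww = x.shape
        ph = x.mean(axis=3, keepdims=True)                       # (B, C, H, 1)
        pw = x.mean(axis=2, keepdims=True).transpose(0, 1, 3, 2)  # (B, C, W, 1)
        y = self.reduce(nn.concat([ph, pw], axis=2))             # (B, mid, H+W, 1)
        yh = y[:, :, :hh, :]
        yw = y[:, :, hh:, :]
        s_h = self.expand_h(yh).sigmoid()                         # (B, C, H, 1)
        s_w = self.expand_w(yw).sigmoid().transpose(0, 1, 3, 2)   # (B, C, 1, W)
        out = x * s_h * s_w
        return out, AttentionWeights(s_h=s_h.data, s_w=s_w.data)


class _ConvBN(nn.Module):
    """1x1 channel-aligning convolution + batch norm (no activation)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, 1, rng, bias=False)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x))


class GlobalFeature(nn.Module):
    """Resize all pyramid levels to the target-stride resolution, concatenate
    along channels and project with a 1x1 convolution."""

    def __init__(self, enc_channels: tuple[int, ...], out_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.project = nn.ConvBNAct(sum(enc_channels), out_channels, 1, rng)

    def forward(self, pyramid: FeaturePyramid, size: tuple[int, int]) -> Tensor:
        resized = [F.interpolate_bilinear(l, size) for l in pyramid.levels]
        return self.project(nn.concat(resized, axis=1))


class DecoderStage(nn.Module):
    def __init__(self, prev_w: int, enc_c: int, w: int, cg: int,
                 rng: np.random.Generator, cfg: DecoderConfig):
        super().__init__()
        self.attention = (ChannelAttention(enc_c, rng, cfg.ca_reduction)
                          if cfg.use_channel_attention else None)
        self.align_prev = _ConvBN(prev_w, w, rng)
        self.align_enc = _ConvBN(enc_c, w, rng)
        self.align_global = _ConvBN(cg, w, rng) if cfg.use_global_fusion else None
        self.fuse = nn.Sequential(*[nn.ConvBNAct(w, w, 3, rng)
                                    for _ in range(cfg.fuse_convs)])

    def forward(self, prev: Tensor, enc: Tensor, g: Tensor | None):
        size = (enc.shape[2], enc.shape[3])
        up = self.align_prev(F.interpolate_bilinear(prev, size))
        if self.attention is not None:
            gated, weights = self.attention(enc)
        else:
            gated, weights = enc, None
        x = up + self.align_enc(gated)
        if self.align_global is not None and g is not None:
            x = x + self.align_global(F.interpolate_bilinear(g, size))
        return self.fuse(x), weights


class FusionDecoder(nn.Module):
    """Reconstructs a full-resolution 2-class score map from the pyramid."""

    def __init__(self, enc_channels: tuple[int, ...], rng: np.random.Generator,
                 config: DecoderConfig | None = None, n_classes: int = 2):
        super().__init__()
        cfg = config or DecoderConfig()
        self.config = cfg
        w = cfg.widths
        self.global_feature = (GlobalFeature(enc_channels, cfg.global_channels, rng)
                               if cfg.use_global_fusion else None)
        self.init_proj = _ConvBN(enc_channels[4], w[0], rng)
        self.stages = [
            DecoderStage(w[0], enc_channels[3], w[0], cfg.global_channels, rng, cfg),
            DecoderStage(w[0], enc_channels[2], w[1], cfg.global_channels, rng, cfg),
            DecoderStage(w[1], enc_channels[1], w[2], cfg.global_channels, rng, cfg),
            DecoderStage(w[2], enc_channels[0], w[3], cfg.global_channels, rng, cfg),
        ]
        self.head_conv = nn.ConvBNAct(w[3], cfg.head_channels, 3, rng)
        self.head = nn.Conv2d(cfg.head_channels, n_classes, 1, rng, bias=True)
        self.last_attention: list[AttentionWeights | None] = []

    def forward(self, pyramid: FeaturePyramid) -> Tensor:
        h2, w2 = pyramid.levels[0].shape[2], pyramid.levels[0].shape[3]
        g = None
        if self.global_feature is not None:
            s = self.config.global_stride
            g = self.global_feature(pyramid, (h2 * 2 // s, w2 * 2 // s))
        x = self.init_proj(pyramid.levels[4])
        self.last_attention = []
        for stage, enc in zip(self.stages, pyramid.levels[3::-1]):
            x, weights = stage(x, enc, g)
            self.last_attention.append(weights)
        x = self.head(self.head_conv(x))
        return F.interpolate_bilinear(x, (h2 * 2, w2 * 2))
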