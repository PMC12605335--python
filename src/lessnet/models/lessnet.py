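"""The assembled segmentation network: hybrid encoder + fusion decoder."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import nn
from ..nn import Tensor
from ..nn import functional as F
from .decoder import DecoderConfig, FusionDecoder
from .mobilevit import EncoderConfig, FeaturePyramid, MobileViTEncoder


@dataclass
class ModelConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    n_classes: int = 2

    @classmethod
    def small(cls) -> "ModelConfig":
        return cls()

    @classmethod
    def tiny_test(cls) -> "ModelConfig":
        return cls(encoder=EncoderConfig.tiny_test(), decoder=DecoderConfig.tiny_test())


class LessNet(nn.Module):
    """Binary segmentation network producing full-resolution 2-class scores."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        super().__init__()
        self.config = config or ModelConfig()
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6E65]))
        self.encoder = MobileViTEncoder(self.config.encoder, rng)
        self.decoder = FusionDecoder(self.config.encoder.stage_channels, rng,
                                     self.config.decoder, self.config.n_classes)

    def forward(self, x: Tensor) -> Tensor:
        pyramid = self.encoder(x)
        return self.decoder(pyramid)

    def encode(self, x: Tensor) -> FeaturePyramid:
        return self.encoder(x)

    def probabilities(self, x: Tensor) -> Tensor:
        """Softmax class probability map p(y|x), shape (B, C, H, W)."""
        return F.softmax(self.forward(x), axis=1)


def build_model(variant: str = "small", seed: int = 0,
                config: ModelConfig | None = None) -> LessNet:
    if config is None:
        config = ModelConfig.tiny_test() if variant in ("tiny-test", "tiny_test", "tiny") \
            else ModelConfig.small()
    return LessNet(config, seed=seed)
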