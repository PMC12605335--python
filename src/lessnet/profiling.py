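"""Model profiling: trainable parameter count and forward-pass FLOPs.

FLOPs are counted during a real forward pass at the requested input size.
The convention is the one common profilers use when printing "GFLOPs": one
multiply-accumulate counts as one operation, and only convolutions, linear
layers and matrix products (including attention) contribute; elementwise
arithmetic, normalisation and interpolation are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import MacCounter, Tensor, no_grad


@dataclass
class ModelProfile:
    parameters_millions: float
    gflops: float
    input_size: tuple[int, int]
    convention: str = "1 MAC = 1 op; conv/linear/matmul only"

    def to_dict(self) -> dict:
        return {"parameters_millions": self.parameters_millions,
                "gflops": self.gflops,
                "input_size": list(self.input_size),
                "convention": self.convention}


def count_parameters(model: nn.Module) -> int:
    """Number of trainable parameters (independent of input size)."""
    return model.num_parameters()


def profile_model(model: nn.Module, input_size: tuple[int, int] = (512, 512)) -> ModelProfile:
    """Profile one forward pass at ``input_size`` (H, W) with batch 1."""
    was_training = model.training
    model.eval()
    x = Tensor(np.zeros((1, 3, input_size[0], input_size[1]), dtype=np.float32))
    with no_grad(), MacCounter() as counter:
        model(x)
    if was_training:
        model.train()
    return ModelProfile(parameters_millions=count_parameters(model) / 1e6,
                        gflops=counter.macs / 1e9,
                        input_size=tuple(input_size))
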