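"""Training objectives.

The total objective is ``L_total = L_supervised + lambda * L_triplet``:

* the supervised term is mean per-pixel cross-entropy on labeled images;
* the unsupervised *triplet consistency* term sums, over every unlabeled
  image, the pairwise squared distances between the softmax probability
  maps of three views of that image — original, weakly augmented and
  strongly augmented — weighted by alpha (orig-weak), beta (orig-strong)
  and gamma (weak-strong), averaged over the batch.

The squared distance is, by default, the mean over pixels and channels of
the squared difference, making the loss magnitude independent of image
resolution; ``reduction="sum"`` gives the plain summed squared-L2 per
image instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor
from .nn import functional as F


@dataclass
class LossWeights:
    lambda_u: float = 1.0   # weight of the consistency term in the total loss
    alpha: float = 1.0      # original vs weak view
    beta: float = 1.0       # original vs strong view
    gamma: float = 1.0      # weak vs strong view
    ramp_epochs: int = 40   # length of the sigmoid warm-up of lambda

    def __post_init__(self):
        if min(self.lambda_u, self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.ramp_epochs < 0:
            raise ValueError("ramp_epochs must be non-negative")


def supervised_loss(logits: Tensor, mask: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy between softmax(logits) and the mask.

    ``logits`` is (B, C, H, W) (or (C, H, W) for one image); ``mask`` holds
    class indices in {0, 1}.
    """
    mask = np.asarray(mask)
    if not np.all(np.isin(np.unique(mask), [0, 1])):
        raise ValueError("mask may contain only class indices 0 and 1")
    if logits.ndim == 3:
        logits = logits.reshape(1, *logits.shape)
        mask = mask.reshape(1, *mask.shape)
    if logits.shape[0] != mask.shape[0] or logits.shape[2:] != mask.shape[1:]:
        raise ValueError(f"logits {logits.shape} and mask {mask.shape} disagree")
    return F.cross_entropy(logits, mask)


def _pair_dist(a: Tensor, b: Tensor, reduction: str) -> Tensor:
    """Per-image squared distance, reduced over channels and pixels; the
    result has shape (B,)."""
    d = (a - b) ** 2
    axes = tuple(range(1, a.ndim))
    return d.mean(axis=axes) if reduction == "mean" else d.sum(axis=axes)


def triplet_consistency_loss(p_orig: Tensor, p_weak: Tensor, p_strong: Tensor,
                             w: LossWeights, reduction: str = "mean") -> Tensor:
    """Batch-mean weighted sum of pairwise squared distances between the
    probability maps of the three views of each unlabeled image."""
    if not (p_orig.shape == p_weak.shape == p_strong.shape):
        raise ValueError("the three probability maps must share one shape")
    if reduction not in ("mean", "sum"):
        raise ValueError("reduction must be 'mean' or 'sum'")
    per_image = (w.alpha * _pair_dist(p_orig, p_weak, reduction)
                 + w.beta * _pair_dist(p_orig, p_strong, reduction)
                 + w.gamma * _pair_dist(p_weak, p_strong, reduction))
    return per_image.mean()


def total_loss(sup: Tensor | float, unsup: Tensor | float, lambda_effective: float):
    """L_total = L_supervised + lambda * L_triplet."""
    return sup + lambda_effective * unsup


def lambda_schedule(epoch: int, w: LossWeights) -> float:
    """Sigmoid-shaped warm-up of the consistency weight.

    Follows the standard exp(-5 (1 - t)^2) ramp of consistency training:
    near zero at epoch 0, exactly ``lambda_u`` from ``ramp_epochs`` on,
    monotone non-decreasing in between.
    """
    if epoch < 0:
        raise ValueError("epoch must be non-negative")
    if w.ramp_epochs == 0 or epoch >= w.ramp_epochs:
        return float(w.lambda_u)
    t = epoch / w.ramp_epochs
    return float(w.lambda_u * np.exp(-5.0 * (1.0 - t) ** 2))
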