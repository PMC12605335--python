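"""Train/test partitioning and the labeled/unlabeled sub-partition.

The study protocol splits the corpus 8:2 into training and testing, then
marks a fraction of the training subset (the label ratio: 5%, 25% or 50%)
as labeled for the supervised loss; the remainder is used unlabeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthetic import ImageSample


@dataclass
class DatasetSplit:
    train: list[ImageSample]
    test: list[ImageSample]
    labeled_ids: set[str]
    label_ratio: float

    def __post_init__(self):
        train_ids = {s.id for s in self.train}
        test_ids = {s.id for s in self.test}
        if train_ids & test_ids:
            raise ValueError("train and test sets share sample ids")
        if not set(self.labeled_ids) <= train_ids:
            raise ValueError("labeled_ids must be a subset of train ids")

    @property
    def labeled(self) -> list[ImageSample]:
        return [s for s in self.train if s.id in self.labeled_ids]

    @property
    def unlabeled(self) -> list[ImageSample]:
        return [s for s in self.train if s.id not in self.labeled_ids]


def labeled_count(n_train: int, label_ratio: float) -> int:
    """floor(label_ratio * n_train); at least one labeled sample is required."""
    n = int(np.floor(label_ratio * n_train))
    if n < 1:
        raise ValueError(
            f"label_ratio {label_ratio} yields zero labeled samples for "
            f"{n_train} training images (at least 1 required)")
    return n


def split_dataset(samples: list[ImageSample], test_fraction: float = 0.2,
                  label_ratio: float = 0.5, seed: int = 0) -> DatasetSplit:
    """Deterministic shuffled train/test split with a uniformly-sampled
    labeled subset of the training portion."""
    if not samples:
        raise ValueError("cannot split an empty sample list")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    if not 0.0 < label_ratio <= 1.0:
        raise ValueError("label_ratio must lie in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x51]))
    order = rng.permutation(len(samples))
    n_test = int(round(test_fraction * len(samples)))
    n_test = min(max(n_test, 1), len(samples) - 1)
    test = [samples[i] for i in order[:n_test]]
    train = [samples[i] for i in order[n_test:]]
    n_labeled = labeled_count(len(train), label_ratio)
    labeled_idx = rng.choice(len(train), size=n_labeled, replace=False)
    labeled_ids = {train[i].id for i in labeled_idx}
    return DatasetSplit(train=train, test=test, labeled_ids=labeled_ids,
                        label_ratio=label_ratio)
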