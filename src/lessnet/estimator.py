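"""Scikit-learn style estimator facade.

``LessNetSegmenter`` wraps the semi-supervised training loop behind the
familiar ``fit`` / ``predict`` / ``score`` contract so it composes with
scikit-learn model selection.  Unlabeled training images follow the
scikit-learn semi-supervised convention: pass their mask filled with -1.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .data.splits import DatasetSplit
from .data.synthetic import ImageSample
from .losses import LossWeights
from .metrics import MetricReport
from .models import DecoderConfig, EncoderConfig, ModelConfig
from .training import TrainConfig, evaluate_model, predict, train


class LessNetSegmenter(BaseEstimator):
    """Semi-supervised binary segmentation estimator.

    Parameters mirror the training configuration: the published recipe is
    SGD with momentum 0.9, learning rate decaying 0.01 -> 0.001, batch
    size 8, 200 epochs at 512x512 input.  ``variant="tiny-test"`` selects
    a drastically narrowed network for CPU-scale experiments.

    Attributes set by :meth:`fit` (trailing underscore): ``model_``,
    ``checkpoint_``, ``history_``.
    """

    def __init__(self, variant: str = "small", image_size: int = 512,
                 epochs: int = 200, batch_size: int = 8,
                 initial_lr: float = 0.01, min_lr: float = 0.001,
                 momentum: float = 0.9, labeled_fraction_per_batch: float = 0.5,
                 lambda_u: float = 1.0, alpha: float = 1.0, beta: float = 1.0,
                 gamma: float = 1.0, ramp_epochs: int = 40,
                 eval_every: int = 1, seed: int = 0):
        self.variant = variant
        self.image_size = image_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.initial_lr = initial_lr
        self.min_lr = min_lr
        self.momentum = momentum
        self.labeled_fraction_per_batch = labeled_fraction_per_batch
        self.lambda_u = lambda_u
        self.alpha = alpha
        self.beta = beta
        self.gamma = gamma
        self.ramp_epochs = ramp_epochs
        self.eval_every = eval_every
        self.seed = seed

    # -- config assembly ------------------------------------------------------
    def _model_config(self) -> ModelConfig:
        if self.variant in ("tiny-test", "tiny_test", "tiny"):
            return ModelConfig.tiny_test()
        return ModelConfig(encoder=EncoderConfig.from_name(self.variant),
                           decoder=DecoderConfig())

    def _loss_config(self) -> LossWeights:
        return LossWeights(lambda_u=self.lambda_u, alpha=self.alpha,
                           beta=self.beta, gamma=self.gamma,
                           ramp_epochs=self.ramp_epochs)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(initial_lr=self.initial_lr, min_lr=self.min_lr,
                           batch_size=self.batch_size, epochs=self.epochs,
                           momentum=self.momentum, image_size=self.image_size,
                           labeled_fraction_per_batch=self.labeled_fraction_per_batch,
                           eval_every=self.eval_every, seed=self.seed)

    @staticmethod
    def _to_samples(X, y=None, prefix: str = "s") -> list[ImageSample]:
        samples = []
        for i, img in enumerate(X):
            mask = None
            if y is not None:
                m = np.asarray(y[i])
                if not (m < 0).all():  # all-negative mask marks "unlabeled"
                    mask = m.astype(np.uint8)
            samples.append(ImageSample(id=f"{prefix}{i:05d}", image=np.asarray(img), mask=mask))
        return samples

    # -- estimator API --------------------------------------------------------
    def fit(self, X, y) -> "LessNetSegmenter":
        """Fit on images ``X`` (N, H, W, 3 uint8) and masks ``y`` (N, H, W).

        Mask entries of -1 mark an image as unlabeled; it participates only
        in the consistency term.
        """
        X = np.asarray(X)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError("X must be (n_samples, H, W, 3)")
        if len(X) != len(y):
            raise ValueError("X and y lengths differ")
        samples = self._to_samples(X, y)
        labeled_ids = {s.id for s in samples if s.mask is not None}
        if not labeled_ids:
            raise ValueError("fit requires at least one labeled image")
        ratio = len(labeled_ids) / len(samples)
        split = DatasetSplit(train=samples, test=[], labeled_ids=labeled_ids,
                             label_ratio=ratio)
        self.checkpoint_, self.history_ = train(
            split, self._model_config(), self._loss_config(), self._train_config())
        self.model_ = self.checkpoint_.build_model()
        return self

    def predict(self, X) -> np.ndarray:
        """Per-pixel class labels, shape (n_samples, H, W), values {0, 1}."""
        self._check_fitted()
        preds, _ = predict(self.model_, self._to_samples(np.asarray(X)))
        return np.stack(preds)

    def predict_proba(self, X) -> np.ndarray:
        """Softmax probability maps, shape (n_samples, 2, H, W)."""
        self._check_fitted()
        _, probs = predict(self.model_, self._to_samples(np.asarray(X)))
        return np.stack(probs)

    def score(self, X, y) -> float:
        """Mean intersection-over-union on the given labeled set."""
        return self.evaluate(X, y).miou

    def evaluate(self, X, y) -> MetricReport:
        """The full metric battery on a labeled set."""
        self._check_fitted()
        samples = self._to_samples(np.asarray(X), y)
        if any(s.mask is None for s in samples):
            raise ValueError("evaluation requires masks for every image")
        return evaluate_model(self.model_, samples)

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")
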