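"""Semi-supervised training loop.

Every optimization step draws a mixed batch: labeled images feed the
supervised cross-entropy, unlabeled images are expanded into the
(original, weak, strong) view triple — three forward passes through the
shared network, so batch-statistics layers see each view's own statistics
— and feed the triplet consistency loss.  The two terms combine as
``L_total = L_sup + lambda(epoch) * L_triplet`` with a sigmoid-ramped
lambda, optimised by SGD with momentum under cosine learning-rate decay.

An *epoch* is one shuffled pass over the labeled pool; the unlabeled pool
is consumed by a reshuffling cyclic iterator (when the labeled pool is the
larger one, the unlabeled side is resampled with replacement).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .data.splits import DatasetSplit
from .data.synthetic import ImageSample
from .losses import (LossWeights, lambda_schedule, supervised_loss,
                     total_loss, triplet_consistency_loss)
from .metrics import MetricReport, evaluate_predictions
from .models import LessNet, ModelConfig
from .models.decoder import DecoderConfig
from .models.mobilevit import EncoderConfig
from .nn import SGD, Tensor, cosine_lr, no_grad
from .nn.modules import frozen_bn_stats
from .nn import concat, functional as F
from .augment import strong_view, weak_view


@dataclass
class TrainConfig:
    initial_lr: float = 0.01
    min_lr: float = 0.001
    batch_size: int = 8
    epochs: int = 200
    momentum: float = 0.9
    image_size: int = 512
    labeled_fraction_per_batch: float = 0.5
    eval_every: int = 1
    align_views: bool = True
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self):
        if self.min_lr > self.initial_lr:
            raise ValueError("min_lr must not exceed initial_lr")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")


@dataclass
class Checkpoint:
    model_state: dict
    optimizer_state: dict
    epoch: int
    best_metric: float
    model_config: dict
    train_config: dict
    loss_config: dict

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {f"model/{k}": v for k, v in self.model_state.items()}
        for i, v in enumerate(self.optimizer_state.get("velocity", [])):
            arrays[f"opt/velocity/{i}"] = v
        meta = {"epoch": self.epoch, "best_metric": self.best_metric,
                "model_config": self.model_config,
                "train_config": self.train_config,
                "loss_config": self.loss_config,
                "opt": {k: v for k, v in self.optimizer_state.items() if k != "velocity"}}
        arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        with open(path, "wb") as f:
            np.savez(f, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(Path(path), allow_pickle=False) as z:
            meta = json.loads(bytes(z["meta_json"]).decode())
            model_state = {k[len("model/"):]: z[k] for k in z.files if k.startswith("model/")}
            vel_keys = sorted((k for k in z.files if k.startswith("opt/velocity/")),
                              key=lambda k: int(k.rsplit("/", 1)[1]))
            opt_state = dict(meta["opt"])
            opt_state["velocity"] = [z[k] for k in vel_keys]
        return cls(model_state=model_state, optimizer_state=opt_state,
                   epoch=meta["epoch"], best_metric=meta["best_metric"],
                   model_config=meta["model_config"],
                   train_config=meta["train_config"],
                   loss_config=meta["loss_config"])

    def build_model(self) -> LessNet:
        cfg = model_config_from_dict(self.model_config)
        model = LessNet(cfg, seed=0)
        model.load_state_dict(self.model_state)
        return model


def model_config_from_dict(d: dict) -> ModelConfig:
    enc = EncoderConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in d["encoder"].items()})
    dec = DecoderConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in d["decoder"].items()})
    return ModelConfig(encoder=enc, decoder=dec, n_classes=d.get("n_classes", 2))


def _to_batch(samples: list[ImageSample]) -> Tensor:
    x = np.stack([s.image for s in samples]).astype(np.float32) / 255.0
    return Tensor(np.ascontiguousarray(x.transpose(0, 3, 1, 2)))


def _align_view(probs: Tensor, params: list[dict]) -> Tensor:
    """Map a view's probability maps back to the original frame by undoing
    the geometric part of the augmentation (rotation, then flip)."""
    angles = np.array([-p.get("angle", 0.0) for p in params])
    if np.any(angles != 0.0):
        probs = F.rotate_bilinear(probs, angles)
    if any(p.get("hflip") for p in params):
        pieces = []
        for b, p in enumerate(params):
            piece = probs[b:b + 1]
            pieces.append(F.flip_w(piece) if p.get("hflip") else piece)
        probs = concat(pieces, axis=0)
    return probs


def _cycler(n: int, rng: np.random.Generator):
    """Yields indices forever, reshuffling after each full pass."""
    while True:
        for i in rng.permutation(n):
            yield int(i)


def train(split: DatasetSplit, model_cfg: ModelConfig | None = None,
          loss_cfg: LossWeights | None = None,
          train_cfg: TrainConfig | None = None,
          model: LessNet | None = None) -> tuple[Checkpoint, dict]:
    """Run the semi-supervised loop; returns the selected checkpoint (best
    test mIoU when a test set is present, else the final state) and the
    loss/metric history."""
    loss_cfg = loss_cfg or LossWeights()
    train_cfg = train_cfg or TrainConfig()
    model_cfg = model_cfg or ModelConfig()
    labeled = split.labeled
    unlabeled = split.unlabeled
    if not labeled:
        raise ValueError("training requires at least one labeled sample")
    for s in labeled:
        if s.mask is None:
            raise ValueError(f"labeled sample {s.id} has no mask")
    if unlabeled and train_cfg.batch_size < 2:
        raise ValueError("batch_size must be >= 2 when unlabeled data is present")

    if model is None:
        model = LessNet(model_cfg, seed=train_cfg.seed)
    n_lab_batch = max(1, int(round(train_cfg.batch_size * train_cfg.labeled_fraction_per_batch)))
    n_unl_batch = train_cfg.batch_size - n_lab_batch if unlabeled else 0
    use_consistency = bool(unlabeled) and loss_cfg.lambda_u > 0

    opt = SGD(model.parameters(), lr=train_cfg.initial_lr, momentum=train_cfg.momentum)
    rng = np.random.default_rng(np.random.SeedSequence([int(train_cfg.seed), 0x7121]))
    unl_iter = _cycler(len(unlabeled), rng) if unlabeled else None
    steps_per_epoch = int(np.ceil(len(labeled) / n_lab_batch))

    history: dict = {"epochs": []}
    best_miou = -1.0
    best_state = None
    best_epoch = -1
    aug_seed_base = int(train_cfg.seed) % (2 ** 24)

    for epoch in range(train_cfg.epochs):
        model.train()
        lr = cosine_lr(epoch, train_cfg.epochs, train_cfg.initial_lr, train_cfg.min_lr)
        opt.lr = lr
        lam = lambda_schedule(epoch, loss_cfg) if use_consistency else 0.0
        lab_order = rng.permutation(len(labeled))
        steps = []
        for step in range(steps_per_epoch):
            idx = lab_order[step * n_lab_batch:(step + 1) * n_lab_batch]
            if len(idx) == 0:
                break
            lab_batch = [labeled[i] for i in idx]
            opt.zero_grad()
            logits = model(_to_batch(lab_batch))
            sup = supervised_loss(logits, np.stack([s.mask for s in lab_batch]))
            unsup_val = 0.0
            if use_consistency and n_unl_batch > 0:
                unl_batch = [unlabeled[next(unl_iter)] for _ in range(n_unl_batch)]
                seeds = [aug_seed_base + 1000003 * epoch + 1009 * step + j
                         for j in range(n_unl_batch)]
                weak_pairs = [weak_view(s, sd) for s, sd in zip(unl_batch, seeds)]
                strong_pairs = [strong_view(s, sd) for s, sd in zip(unl_batch, seeds)]
                p_o = F.softmax(model(_to_batch(unl_batch)), axis=1)
                with frozen_bn_stats():  # views must not skew running stats
                    p_w = F.softmax(model(_to_batch([v for v, _ in weak_pairs])), axis=1)
                    p_s = F.softmax(model(_to_batch([v for v, _ in strong_pairs])), axis=1)
                if train_cfg.align_views:
                    p_w = _align_view(p_w, [p for _, p in weak_pairs])
                    p_s = _align_view(p_s, [p for _, p in strong_pairs])
                unsup = triplet_consistency_loss(p_o, p_w, p_s, loss_cfg)
                loss = total_loss(sup, unsup, lam)
                unsup_val = unsup.item()
            else:
                loss = sup
            loss_val = loss.item()
            if not np.isfinite(loss_val):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} step {step}: "
                    f"sup={sup.item():.4g} unsup={unsup_val:.4g} lr={lr:.4g}")
            loss.backward()
            opt.step()
            steps.append({"sup": sup.item(), "unsup": unsup_val,
                          "lambda": lam, "total": loss_val})
        record = {"epoch": epoch, "lr": lr, "lambda": lam,
                  "sup": float(np.mean([s["sup"] for s in steps])),
                  "unsup": float(np.mean([s["unsup"] for s in steps])),
                  "total": float(np.mean([s["total"] for s in steps])),
                  "steps": steps}
        if split.test and (epoch % train_cfg.eval_every == 0
                           or epoch == train_cfg.epochs - 1):
            report = evaluate_model(model, split.test)
            record["test_miou"] = report.miou
            record["test_dice"] = report.dice
            if report.miou > best_miou:
                best_miou = report.miou
                best_state = model.state_dict()
                best_epoch = epoch
        history["epochs"].append(record)

    if best_state is None:
        best_state = model.state_dict()
        best_epoch = train_cfg.epochs - 1
    ckpt = Checkpoint(model_state=best_state,
                      optimizer_state=opt.state_dict(),
                      epoch=best_epoch, best_metric=best_miou,
                      model_config=asdict(model_cfg),
                      train_config=asdict(train_cfg),
                      loss_config=asdict(loss_cfg))
    return ckpt, history


def predict(model: LessNet, samples: list[ImageSample], batch_size: int = 8
            ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Argmax class maps and softmax probability maps for ``samples``."""
    model.eval()
    preds, probs = [], []
    with no_grad():
        for i in range(0, len(samples), batch_size):
            batch = samples[i:i + batch_size]
            p = F.softmax(model(_to_batch(batch)), axis=1).data
            # argmax with ties resolved to the lower class index
            pred = np.argmax(p, axis=1).astype(np.uint8)
            for j in range(len(batch)):
                preds.append(pred[j])
                probs.append(p[j])
    return preds, probs


def evaluate_model(model: LessNet, samples: list[ImageSample],
                   batch_size: int = 8) -> MetricReport:
    if not samples:
        raise ValueError("cannot evaluate on an empty sample list")
    for s in samples:
        if s.mask is None:
            raise ValueError(f"evaluation sample {s.id} has no mask")
    preds, probs = predict(model, samples, batch_size)
    truths = [s.mask for s in samples]
    return evaluate_predictions(preds, truths, probs=probs)


def evaluate(checkpoint: Checkpoint, samples: list[ImageSample],
             batch_size: int = 8) -> MetricReport:
    """Rebuild the checkpointed model and run the full metric battery."""
    return evaluate_model(checkpoint.build_model(), samples, batch_size)
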