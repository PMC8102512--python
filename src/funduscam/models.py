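"""Small CNN grade classifiers exposing the internals Grad-CAM needs.

Four architecture variants carry the distinguishing motifs of the large
networks used for diabetic-retinopathy grading in the literature:

- ``plain``       — a straight convolutional stack,
- ``residual``    — additive skip connections (ResNet motif),
- ``multibranch`` — parallel convolution branches concatenated channel-wise
  (Inception motif),
- ``separable``   — depth-wise followed by point-wise convolutions
  (Xception motif).

Each model ends with a tagged last convolutional layer, global average
pooling and a 5-way softmax head over DR grades 0-4. Training follows a
two-phase schedule: the classifier head alone first, then the full model
with early stopping on validation loss and best-weight restoration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn

VARIANTS = ("plain", "residual", "multibranch", "separable")


@dataclass
class ModelConfig:
    variant: str = "plain"
    input_size: int = 128
    base_channels: int = 8
    num_classes: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.input_size < 8 or self.input_size % 4 != 0:
            raise ValueError("input_size must be >= 8 and divisible by 4")
        if self.num_classes != 5:
            raise ValueError("num_classes must be 5 (DR grades 0-4)")


@dataclass
class TrainConfig:
    """Two-phase schedule: head-only warm-up, then full-model fine-tuning."""

    head_epochs: int = 5
    full_epochs: int = 100
    patience: int = 20
    learning_rate: float = 0.001
    batch_size: int = 32
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.full_epochs and self.patience > self.full_epochs:
            raise ValueError("patience must be <= full_epochs")


class EarlyStopper:
    """Stop when the monitored loss has not improved for `patience` epochs."""

    def __init__(self, patience: int) -> None:
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.stale = 0

    def update(self, epoch: int, loss: float) -> bool:
        """Record one epoch; return True when training should stop."""
        if loss < self.best - 1e-12:
            self.best = loss
            self.best_epoch = epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


class GraderModel:
    """A CNN grade classifier with a tagged last convolutional layer."""

    def __init__(self, config: ModelConfig) -> None:
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config.base_channels
        v = config.variant

        def conv_relu(cin, cout, name):
            return [nn.Conv2D(cin, cout, 3, rng, name), nn.ReLU()]

        stem = conv_relu(3, c, "stem") + [nn.MaxPool2D()]
        if v == "plain":
            mid = conv_relu(c, 2 * c, "mid") + [nn.MaxPool2D()]
        elif v == "residual":
            body = nn.Sequential(
                conv_relu(c, c, "res.a") + [nn.Conv2D(c, c, 3, rng, "res.b")]
            )
            mid = [nn.Residual(body), nn.ReLU()] + conv_relu(c, 2 * c, "mid") + [nn.MaxPool2D()]
        elif v == "multibranch":
            block = nn.Parallel([
                nn.Sequential([nn.Conv2D(c, c, 1, rng, "br1x1")]),
                nn.Sequential(conv_relu(c, c, "br3x3.a")[:1] + [nn.ReLU(), nn.Conv2D(c, c, 3, rng, "br3x3.b")]),
            ])
            mid = [block, nn.ReLU(), nn.MaxPool2D()]
        elif v == "separable":
            mid = [
                nn.DepthwiseConv2D(c, 3, rng, "sep.dw"),
                nn.Conv2D(c, 2 * c, 1, rng, "sep.pw"),
                nn.ReLU(),
                nn.MaxPool2D(),
            ]
        self.last_conv = nn.Conv2D(2 * c, 2 * c, 3, rng, "last_conv")
        self.features = nn.Sequential(stem + mid + [self.last_conv, nn.ReLU()])
        self.pool = nn.GlobalAvgPool()
        self.head = nn.Dense(2 * c, config.num_classes, rng, "head")
        self.layer_id = self.last_conv.name

    # ---- inference -----------------------------------------------------

    def logits(self, x: np.ndarray) -> np.ndarray:
        return self.head.forward(self.pool.forward(self.features.forward(x)))

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Class probabilities over grades 0-4; images NHWC in [0, 1]."""
        x = np.atleast_1d(np.asarray(images, dtype=np.float64))
        if x.ndim == 3:
            x = x[None]
        if x.shape[1] != self.config.input_size or x.shape[2] != self.config.input_size:
            raise ValueError(
                f"image shape {x.shape[1:3]} does not match input_size {self.config.input_size}"
            )
        return nn.softmax(self.logits(x))

    def predict(self, images: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(images), axis=-1)

    def class_score_gradients(
        self, image: np.ndarray, target_class: int
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Activations A of the last conv layer, d(score)/dA, and probs.

        The target score is the pre-softmax logit of ``target_class``.
        """
        x = np.asarray(image, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        logits = self.logits(x)
        probs = nn.softmax(logits)[0]
        dlogits = np.zeros_like(logits)
        dlogits[:, target_class] = 1.0
        self._zero_grads()
        self.features.backward(self.pool.backward(self.head.backward(dlogits)))
        acts = self.last_conv.cached_out[0]
        grads = self.last_conv.cached_dout[0]
        if not (np.isfinite(acts).all() and np.isfinite(grads).all()):
            raise FloatingPointError("non-finite activations or gradients")
        return acts, grads, probs

    # ---- parameters ----------------------------------------------------

    def all_params(self) -> list[nn.Param]:
        return self.features.params() + self.head.params()

    def head_params(self) -> list[nn.Param]:
        return self.head.params()

    def _zero_grads(self) -> None:
        for p in self.all_params():
            p.grad[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.all_params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.all_params(), weights, strict=True):
            p.value[...] = w

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path, **{f"p{i}": w for i, w in enumerate(self.get_weights())})
        cfg_path = path.with_suffix(".json")
        cfg_path.write_text(json.dumps(self.config.__dict__, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "GraderModel":
        path = Path(path)
        cfg = ModelConfig(**json.loads(path.with_suffix(".json").read_text()))
        model = cls(cfg)
        with np.load(path if path.suffix else path.with_suffix(".npz")) as data:
            model.set_weights([data[f"p{i}"] for i in range(len(data.files))])
        return model


def build_model(config: ModelConfig) -> GraderModel:
    return GraderModel(config)


def structural_motifs(model: GraderModel) -> dict[str, bool]:
    """Which architecture motifs are structurally present in the model graph."""
    mods = list(model.features.modules())
    return {
        "residual": any(isinstance(m, nn.Residual) for m in mods),
        "multibranch": any(
            isinstance(m, nn.Parallel) and len(m.branches) >= 2 for m in mods
        ),
        "separable": any(
            isinstance(m, nn.DepthwiseConv2D) for m in mods
        ) and any(isinstance(m, nn.Conv2D) and m.k == 1 for m in mods),
    }


def _run_epoch(model, optimizer, x, y, rng):
    order = rng.permutation(len(x))
    bs = optimizer["batch_size"]
    opt = optimizer["opt"]
    losses = []
    correct = 0
    for start in range(0, len(x), bs):
        idx = order[start : start + bs]
        logits = model.logits(x[idx])
        loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss")
        opt.zero_grad()
        model.features.backward(model.pool.backward(model.head.backward(dlogits)))
        opt.step()
        losses.append(loss * len(idx))
        correct += int((np.argmax(logits, -1) == y[idx]).sum())
    return sum(losses) / len(x), correct / len(x)


def evaluate_loss(model: GraderModel, x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    logits = model.logits(x)
    loss, _ = nn.softmax_cross_entropy(logits, y)
    acc = float((np.argmax(logits, -1) == y).mean())
    return loss, acc


def train(
    model: GraderModel,
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    cfg: TrainConfig,
) -> pd.DataFrame:
    """Two-phase training; returns the per-epoch history.

    Phase 1 updates only the classifier head (convolutional weights frozen);
    phase 2 fine-tunes the full model with early stopping on validation
    loss and restores the best-validation weights at the end.
    """
    cfg.validate()
    if len(train_x) == 0 or len(val_x) == 0:
        raise ValueError("empty training or validation split")
    rng = np.random.default_rng(cfg.seed)
    rows = []

    def log(phase, epoch, tr_loss, tr_acc):
        val_loss, val_acc = evaluate_loss(model, val_x, val_y)
        rows.append({
            "phase": phase, "epoch": len(rows), "train_loss": tr_loss,
            "train_acc": tr_acc, "val_loss": val_loss, "val_acc": val_acc,
        })
        return val_loss

    opt = {"opt": nn.Adam(model.head_params(), lr=cfg.learning_rate),
           "batch_size": cfg.batch_size}
    for epoch in range(cfg.head_epochs):
        tr_loss, tr_acc = _run_epoch(model, opt, train_x, train_y, rng)
        log("head", epoch, tr_loss, tr_acc)

    if cfg.full_epochs > 0:
        opt = {"opt": nn.Adam(model.all_params(), lr=cfg.learning_rate),
               "batch_size": cfg.batch_size}
        stopper = EarlyStopper(cfg.patience)
        best_weights = model.get_weights()
        best_recorded = np.inf
        for epoch in range(cfg.full_epochs):
            tr_loss, tr_acc = _run_epoch(model, opt, train_x, train_y, rng)
            val_loss = log("full", epoch, tr_loss, tr_acc)
            if val_loss < best_recorded:
                best_recorded = val_loss
                best_weights = model.get_weights()
            if stopper.update(epoch, val_loss):
                break
        model.set_weights(best_weights)

    return pd.DataFrame(rows)
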