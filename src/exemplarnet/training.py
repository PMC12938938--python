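"""Network training: SGD with momentum, stratified 70:30 train/validation split.

All stochasticity (split, shuffling; weight init happens at build time) flows
from ``TrainConfig.seed``, so a rerun with the same data, model seed and config
reproduces the final weights bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import train_test_split

from .architecture import LiteNeXt
from .data import load_image_folder
from .errors import ConfigurationError, DataError, TrainingDivergenceError
from .nn import SGDMomentum, softmax_cross_entropy


@dataclass
class TrainConfig:
    solver: str = "sgdm"
    learning_rate: float = 0.01
    momentum: float = 0.9
    max_epochs: int = 100
    batch_size: int = 32
    train_val_ratio: tuple[int, int] = (70, 30)
    seed: int = 0

    def validate(self) -> None:
        if self.solver != "sgdm":
            raise ConfigurationError(f"unsupported solver {self.solver!r}")
        if sum(self.train_val_ratio) != 100:
            raise ConfigurationError("train_val_ratio components must sum to 100")
        if self.max_epochs < 0 or self.batch_size < 1:
            raise ConfigurationError("epoch/batch counts must be positive")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be > 0")


def _recompute_bn_stats(model: LiteNeXt, X: np.ndarray, batch_size: int) -> None:
    """Re-estimate batch-norm running statistics with a full pass over the
    training set at the current weights.

    During short runs the exponential running average lags far behind the
    rapidly moving weights, making inference-mode outputs unrepresentative;
    recomputing the statistics after each epoch (as reference training
    pipelines do after training) keeps validation metrics honest.
    """
    bns = model._norm_layers()
    saved = [(bn.momentum, bn.running_mean.copy(), bn.running_var.copy())
             for bn in bns]
    for bn in bns:
        bn.running_mean[...] = 0.0
        bn.running_var[...] = 0.0
    k = 0
    for start in range(0, X.shape[0], batch_size):
        k += 1
        for bn in bns:
            bn.momentum = 1.0 / k       # cumulative average over batches
        model.logits_batch(X[start:start + batch_size], train=True)
    for bn, (momentum, _, _) in zip(bns, saved):
        bn.momentum = momentum


def _evaluate(model: LiteNeXt, X: np.ndarray, y: np.ndarray,
              batch_size: int) -> tuple[float, float]:
    losses, correct = [], 0
    for start in range(0, X.shape[0], batch_size):
        xb, yb = X[start:start + batch_size], y[start:start + batch_size]
        logits = model.logits_batch(xb, train=False)
        loss, _ = softmax_cross_entropy(logits, yb)
        losses.append(loss * len(yb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / X.shape[0]), correct / X.shape[0]


def train_on_arrays(model: LiteNeXt, X: np.ndarray, y: np.ndarray,
                    config: TrainConfig) -> tuple[LiteNeXt, list[dict]]:
    """Train on an in-memory NCHW array with a stratified 70:30 split."""
    config.validate()
    y = np.asarray(y, dtype=np.int64)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise DataError("training requires at least 2 classes")
    if counts.min() < 2:
        small = classes[counts.argmin()]
        raise DataError(
            f"class {small} has {counts.min()} sample(s); every class needs at "
            f"least one sample in both stratified splits")
    val_frac = config.train_val_ratio[1] / 100.0
    idx_train, idx_val = train_test_split(
        np.arange(y.shape[0]), test_size=val_frac, stratify=y,
        random_state=config.seed % (2 ** 32))
    Xtr, ytr = X[idx_train], y[idx_train]
    Xval, yval = X[idx_val], y[idx_val]
    optimizer = SGDMomentum(model.parameters(), learning_rate=config.learning_rate,
                            momentum=config.momentum)
    rng = np.random.default_rng(config.seed + 1)
    trace: list[dict] = []
    for epoch in range(1, config.max_epochs + 1):
        perm = rng.permutation(Xtr.shape[0])
        epoch_loss, epoch_correct = 0.0, 0
        for start in range(0, perm.size, config.batch_size):
            sel = perm[start:start + config.batch_size]
            xb, yb = Xtr[sel], ytr[sel]
            logits = model.logits_batch(xb, train=True)
            loss, dlogits = softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise TrainingDivergenceError(epoch)
            optimizer.zero_grad()
            model.backward(dlogits)
            optimizer.step()
            epoch_loss += loss * len(yb)
            epoch_correct += int((logits.argmax(axis=1) == yb).sum())
        _recompute_bn_stats(model, Xtr, config.batch_size)
        val_loss, val_acc = _evaluate(model, Xval, yval, config.batch_size)
        trace.append({
            "epoch": epoch,
            "train_loss": epoch_loss / perm.size,
            "train_acc": epoch_correct / perm.size,
            "val_loss": val_loss,
            "val_acc": val_acc,
        })
    return model, trace


def train_model(model: LiteNeXt, dataset, config: TrainConfig,
                ) -> tuple[LiteNeXt, list[dict]]:
    """Train on a labeled image folder (``<root>/<class>/*.png``) or an
    ``(X, y)`` array pair; returns the trained model and the per-epoch trace
    (train/val loss and accuracy, ready for learning-curve plots)."""
    if isinstance(dataset, tuple):
        X, y = dataset
    else:
        X, y, _, _ = load_image_folder(dataset, model.spec.input_side)
    return train_on_arrays(model, np.asarray(X, dtype=np.float32), y, config)
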