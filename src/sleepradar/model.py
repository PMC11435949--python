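"""Posture classifier: configuration, builders, and a scikit-learn estimator.

`ResTCNClassifier` wraps the numpy network behind the scikit-learn estimator
contract (``fit`` / ``predict`` / ``predict_proba`` / ``get_params``), so it
composes with sklearn model selection. Inputs are stacks of feature images
shaped (n_samples, K1, N_W); targets may be hard class indices or soft
(mix-up) probability vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from .nn.layers import BatchNorm, Module
from .nn.loss import softmax, softmax_cross_entropy
from .nn.network import build_network
from .nn.optim import AdamW

VARIANTS = ("restcn", "resnet_only", "tcn_only")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters of the posture networks."""

    n_classes: int = 3
    input_shape: tuple[int, int] = (40, 60)  # (K1, N_W); channel cloning to 3 is internal
    stage_channels: tuple[int, ...] = (16, 32, 64)
    embedding_dim: int = 1024
    tcn_channels: tuple[int, ...] = (64, 64, 64)
    tcn_kernel: int = 3
    tcn_dilations: tuple[int, ...] = (1, 2, 4)
    dropout: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")


def build_restcn(config: ModelConfig) -> Module:
    """The full residual + temporal-convolution classifier."""
    return build_variant("restcn", config)


def build_variant(name: str, config: ModelConfig) -> Module:
    """Build "restcn" or one of the ablation variants ("resnet_only", "tcn_only")."""
    return build_network(
        name,
        input_shape=config.input_shape,
        n_classes=config.n_classes,
        stage_channels=config.stage_channels,
        embedding_dim=config.embedding_dim,
        tcn_channels=config.tcn_channels,
        tcn_kernel=config.tcn_kernel,
        tcn_dilations=config.tcn_dilations,
        dropout=config.dropout,
        seed=config.seed,
    )


def _state_dict(net: Module) -> list:
    state = [(mod, name, mod.params[name].copy()) for mod, name in net.parameters()]
    bn = [(m, m.running_mean.copy(), m.running_var.copy())
          for m in _walk(net) if isinstance(m, BatchNorm)]
    return [state, bn]


def _load_state(net: Module, state: list) -> None:
    for mod, name, arr in state[0]:
        mod.params[name] = arr.copy()
    for mod, mean, var in state[1]:
        mod.running_mean = mean.copy()
        mod.running_var = var.copy()


def _walk(net: Module):
    yield net
    for child in net.children:
        yield from _walk(child)


class ResTCNClassifier(ClassifierMixin, BaseEstimator):
    """Sleep-posture classifier over motion-feature images.

    Trains with AdamW on soft-label cross-entropy, with the step learning-
    rate schedule (initial 0.005, scaled by 0.1 every 10 epochs). The full
    schedule is always run and the final-epoch weights are kept; a supplied
    validation set is used for per-epoch monitoring only (subject-wise
    validation sets here are one or two subjects, far too small to select
    checkpoints reliably).

    Parameters mirror :class:`ModelConfig` and the training recipe; all are
    plain constructor arguments so sklearn cloning and grid search work.
    """

    def __init__(
        self,
        variant: str = "restcn",
        n_classes: int = 3,
        stage_channels: tuple = (16, 32, 64),
        embedding_dim: int = 1024,
        tcn_channels: tuple = (64, 64, 64),
        tcn_kernel: int = 3,
        tcn_dilations: tuple = (1, 2, 4),
        dropout: float = 0.2,
        learning_rate: float = 0.005,
        weight_decay: float = 0.001,
        lr_decay_factor: float = 0.1,
        lr_decay_every_epochs: int = 10,
        epochs: int = 100,
        batch_size: int = 32,
        random_state: int = 0,
    ) -> None:
        self.variant = variant
        self.n_classes = n_classes
        self.stage_channels = stage_channels
        self.embedding_dim = embedding_dim
        self.tcn_channels = tcn_channels
        self.tcn_kernel = tcn_kernel
        self.tcn_dilations = tcn_dilations
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.lr_decay_factor = lr_decay_factor
        self.lr_decay_every_epochs = lr_decay_every_epochs
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 3:
            raise ValueError("X must be (n_samples, K1, N_W) feature images")
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite values")
        return X

    def _soft_targets(self, y, n: int) -> np.ndarray:
        y = np.asarray(y)
        if y.ndim == 1:
            targets = np.zeros((n, self.n_classes), dtype=np.float64)
            targets[np.arange(n), y.astype(int)] = 1.0
            return targets
        if y.shape != (n, self.n_classes):
            raise ValueError(f"soft labels must be (n, {self.n_classes})")
        if np.any(y < 0) or not np.allclose(y.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("soft labels must be probability vectors")
        return y.astype(np.float64)

    def fit(self, X, y, validation_data=None):
        """Train on feature images; ``y`` may be class indices or soft labels.

        ``validation_data`` is an optional ``(X_val, y_val)`` pair used for
        per-epoch monitoring (recorded in ``history_``).
        """
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        X = self._validate_X(X)
        if X.shape[0] == 0:
            raise ValueError("training set is empty")
        targets = self._soft_targets(y, X.shape[0])

        config = ModelConfig(
            n_classes=self.n_classes,
            input_shape=X.shape[1:],
            stage_channels=tuple(self.stage_channels),
            embedding_dim=self.embedding_dim,
            tcn_channels=tuple(self.tcn_channels),
            tcn_kernel=self.tcn_kernel,
            tcn_dilations=tuple(self.tcn_dilations),
            dropout=self.dropout,
            seed=self.random_state,
        )
        net = build_variant(self.variant, config)
        # one global scale keeps absolute feature amplitude informative
        scale = float(X.std())
        self.scale_ = scale if scale > 0 else 1.0
        X = X / self.scale_

        val = None
        if validation_data is not None:
            Xv = self._validate_X(validation_data[0]) / self.scale_
            yv = np.asarray(validation_data[1])
            yv_hard = yv if yv.ndim == 1 else np.argmax(yv, axis=1)
            val = (Xv, yv_hard)

        rng = np.random.default_rng(np.random.SeedSequence([self.random_state, 0x7A1]))
        optimizer = AdamW(net.parameters(), lr=self.learning_rate,
                          weight_decay=self.weight_decay)
        history = []
        n = X.shape[0]
        for epoch in range(self.epochs):
            lr = self.learning_rate * self.lr_decay_factor ** (
                epoch // self.lr_decay_every_epochs)
            optimizer.lr = lr
            order = rng.permutation(n)
            net.set_training(True)
            losses, correct, seen = [], 0, 0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = net.forward(X[idx])
                loss, probs, grad = softmax_cross_entropy(logits, targets[idx])
                net.backward(grad)
                optimizer.step()
                losses.append(loss * idx.size)
                correct += int((np.argmax(probs, axis=1)
                                == np.argmax(targets[idx], axis=1)).sum())
                seen += idx.size
            record = {
                "epoch": epoch,
                "lr": lr,
                "train_loss": float(np.sum(losses) / seen),
                "train_accuracy": correct / seen,
            }
            if val is not None:
                probs = self._forward_eval(net, val[0])
                record["val_accuracy"] = float((np.argmax(probs, axis=1) == val[1]).mean())
            history.append(record)

        self.net_ = net
        self.net_input_shape_ = tuple(X.shape[1:])
        self.classes_ = np.arange(self.n_classes)
        self.history_ = pd.DataFrame(history)
        self.n_parameters_ = net.n_parameters()
        return self

    def _forward_eval(self, net, X, batch: int = 256) -> np.ndarray:
        net.set_training(False)
        chunks = [softmax(net.forward(X[i : i + batch]))
                  for i in range(0, X.shape[0], batch)]
        return np.concatenate(chunks, axis=0)

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise RuntimeError("classifier is not fitted")
        X = self._validate_X(X) / self.scale_
        return self._forward_eval(self.net_, X)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def describe_network(net: Module) -> str:
    """One line per layer with its class and parameter count."""
    lines = []

    def _visit(module: Module, depth: int) -> None:
        own = sum(v.size for v in module.params.values())
        lines.append(f"{'  ' * depth}{type(module).__name__}: {own} params")
        for child in module.children:
            _visit(child, depth + 1)

    _visit(net, 0)
    lines.append(f"total: {net.n_parameters()} params")
    return "\n".join(lines)


def save_classifier(clf: ResTCNClassifier, path) -> None:
    """Persist a fitted classifier (hyperparameters + weights) to one .npz."""
    if not hasattr(clf, "net_"):
        raise RuntimeError("classifier is not fitted")
    arrays = {}
    for i, (mod, name) in enumerate(clf.net_.parameters()):
        arrays[f"p{i}"] = mod.params[name]
    bn = [m for m in _walk(clf.net_) if isinstance(m, BatchNorm)]
    for i, m in enumerate(bn):
        arrays[f"bn{i}_mean"] = m.running_mean
        arrays[f"bn{i}_var"] = m.running_var
    import json

    meta = {k: (list(v) if isinstance(v, tuple) else v)
            for k, v in clf.get_params().items()}
    meta["scale_"] = clf.scale_
    meta["input_shape"] = [int(s) for s in clf.net_input_shape_]
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_classifier(path) -> ResTCNClassifier:
    import json

    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        scale = meta.pop("scale_")
        input_shape = tuple(meta.pop("input_shape"))
        for key in ("stage_channels", "tcn_channels", "tcn_dilations"):
            meta[key] = tuple(meta[key])
        clf = ResTCNClassifier(**meta)
        config = ModelConfig(
            n_classes=clf.n_classes,
            input_shape=input_shape,
            stage_channels=clf.stage_channels,
            embedding_dim=clf.embedding_dim,
            tcn_channels=clf.tcn_channels,
            tcn_kernel=clf.tcn_kernel,
            tcn_dilations=clf.tcn_dilations,
            dropout=clf.dropout,
            seed=clf.random_state,
        )
        net = build_variant(clf.variant, config)
        for i, (mod, name) in enumerate(net.parameters()):
            mod.params[name] = data[f"p{i}"].copy()
        bn = [m for m in _walk(net) if isinstance(m, BatchNorm)]
        for i, m in enumerate(bn):
            m.running_mean = data[f"bn{i}_mean"].copy()
            m.running_var = data[f"bn{i}_var"].copy()
    clf.net_ = net
    clf.scale_ = scale
    clf.classes_ = np.arange(clf.n_classes)
    clf.n_parameters_ = net.n_parameters()
    clf.net_input_shape_ = input_shape
    return clf
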