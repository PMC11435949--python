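"""Subject-wise splitting, the training recipe, and evaluation metrics.

Evaluation follows the one-vs-rest reading of the binary formulas: per class
c the confusion matrix yields TP, FP, FN, TN; precision = TP/(TP+FP),
recall = TP/(TP+FN), F1 their harmonic mean; the reported scores are the
macro averages over the three classes, and accuracy is the confusion trace
over the sample count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

from .features import MotionFeatureImage
from .model import ResTCNClassifier
from .nn.loss import cross_entropy_loss  # noqa: F401  (re-exported surface)
from .radar import CLASS_NAMES


@dataclass(frozen=True)
class TrainConfig:
    """Optimization recipe: AdamW, step learning-rate schedule.

    Defaults are the full recipe (initial LR 0.005, L2 coefficient 0.001,
    LR scaled down 10x every 10 epochs, 100 epochs); benchmark runs in this
    package shorten ``epochs``.
    """

    initial_lr: float = 0.005
    weight_decay: float = 0.001
    lr_decay_factor: float = 0.1
    lr_decay_every_epochs: int = 10
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_lr <= 0:
            raise ValueError("initial_lr must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint subject-level partition of a dataset."""

    train_subjects: tuple[str, ...]
    val_subjects: tuple[str, ...]
    test_subjects: tuple[str, ...]

    def __post_init__(self) -> None:
        groups = (set(self.train_subjects), set(self.val_subjects), set(self.test_subjects))
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("split groups must be pairwise disjoint")

    def split_of(self, subject_id: str) -> str:
        if subject_id in self.train_subjects:
            return "train"
        if subject_id in self.val_subjects:
            return "val"
        if subject_id in self.test_subjects:
            return "test"
        raise KeyError(subject_id)


def subject_split(
    subject_ids: Sequence[str], n_train: int, n_val: int, n_test: int, seed: int = 0
) -> SplitSpec:
    """Seeded random partition at the subject level (never at the sample level)."""
    subjects = sorted(set(subject_ids))
    if n_train + n_val + n_test != len(subjects):
        raise ValueError(
            f"split sizes {n_train}+{n_val}+{n_test} != {len(subjects)} distinct subjects"
        )
    order = np.random.default_rng(seed).permutation(len(subjects))
    shuffled = [subjects[i] for i in order]
    return SplitSpec(
        train_subjects=tuple(shuffled[:n_train]),
        val_subjects=tuple(shuffled[n_train : n_train + n_val]),
        test_subjects=tuple(shuffled[n_train + n_val :]),
    )


def images_to_arrays(images: Sequence[MotionFeatureImage]):
    """Stack feature images into (X, soft_labels, subject_ids) arrays."""
    if not images:
        raise ValueError("empty image set")
    X = np.stack([img.values for img in images]).astype(np.float32)
    y = np.stack([img.label for img in images])
    subjects = np.array([img.subject_id for img in images])
    return X, y, subjects


def partition_images(images: Sequence[MotionFeatureImage], spec: SplitSpec):
    """Group images by the subject-wise split: dict with train/val/test lists."""
    out = {"train": [], "val": [], "test": []}
    for img in images:
        out[spec.split_of(img.subject_id)].append(img)
    return out


@dataclass
class EvalReport:
    """Confusion matrix plus accuracy and per-class/macro precision, recall, F1."""

    confusion: np.ndarray  # rows = true class, cols = predicted
    accuracy: float
    precision: np.ndarray  # per class
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    n_samples: int
    absent_classes: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "class_names": list(CLASS_NAMES),
            "accuracy": self.accuracy,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "n_samples": self.n_samples,
            "absent_classes": list(self.absent_classes),
        }


def report_from_predictions(y_true: np.ndarray, y_pred: np.ndarray,
                            n_classes: int = 3) -> EvalReport:
    """Build the evaluation report from hard labels and predictions."""
    labels = np.arange(n_classes)
    confusion = confusion_matrix(y_true, y_pred, labels=labels)
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    absent = tuple(int(c) for c in labels if not np.any(np.asarray(y_true) == c))
    n = int(confusion.sum())
    return EvalReport(
        confusion=confusion,
        accuracy=float(np.trace(confusion) / n),
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        n_samples=n,
        absent_classes=absent,
    )


def train(
    train_images: Sequence[MotionFeatureImage],
    val_images: Sequence[MotionFeatureImage] | None = None,
    config: TrainConfig | None = None,
    variant: str = "restcn",
    **model_kwargs,
) -> ResTCNClassifier:
    """Fit a posture classifier on feature images with the standard recipe."""
    config = config or TrainConfig()
    if not train_images:
        raise ValueError("training set is empty")
    X, y, _ = images_to_arrays(train_images)
    validation = None
    if val_images:
        Xv, yv, _ = images_to_arrays(val_images)
        validation = (Xv, yv)
    clf = ResTCNClassifier(
        variant=variant,
        learning_rate=config.initial_lr,
        weight_decay=config.weight_decay,
        lr_decay_factor=config.lr_decay_factor,
        lr_decay_every_epochs=config.lr_decay_every_epochs,
        epochs=config.epochs,
        batch_size=config.batch_size,
        random_state=config.seed,
        **model_kwargs,
    )
    clf.fit(X, y, validation_data=validation)
    return clf


def evaluate(clf: ResTCNClassifier, images: Sequence[MotionFeatureImage]) -> EvalReport:
    """Evaluate a fitted classifier on hard-labelled feature images."""
    if not images:
        raise ValueError("evaluation set is empty")
    X, y, _ = images_to_arrays(images)
    y_hard = np.argmax(y, axis=1)
    y_pred = clf.predict(X)
    return report_from_predictions(y_hard, y_pred, n_classes=clf.n_classes)
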