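"""Dataset bookkeeping and diagnostic metrics.

Covers stratified train/validation/test splitting (80:20 of 80%, i.e. per
class of 1000 images: 640 train, 160 validation, 200 test), 8× training-set
augmentation, multiclass confusion matrices, one-vs-rest accuracy /
precision / sensitivity / specificity, ROC AUC, pixelwise mask scoring and
the size-weighted aggregation of per-class accuracies into an overall
accuracy.

All rates are reported in percent; published tables round to one decimal,
and :func:`overall_accuracy` follows that convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.metrics import roc_curve, auc as _auc

from .errors import DataError, ParameterError

__all__ = [
    "KVASIR_CLASSES",
    "LabelledDataset",
    "SplitResult",
    "split_dataset",
    "augment",
    "confusion",
    "ConfusionMatrix",
    "metrics",
    "MetricsReport",
    "overall_accuracy",
    "roc_auc",
    "mask_scores",
]

#: The five endoscopy classes the pipeline is built around.
KVASIR_CLASSES = [
    "dyed-lifted-polyps",
    "normal-cecum",
    "normal-pylorus",
    "polyps",
    "ulcerative-colitis",
]


@dataclass
class LabelledDataset:
    """Items (images or feature rows) with labels from a fixed class list."""

    items: list
    labels: list
    classes: list = field(default_factory=lambda: list(KVASIR_CLASSES))
    role: str | None = None  # train | validation | test | None
    masks: list | None = None

    def __post_init__(self) -> None:
        if len(self.items) != len(self.labels):
            raise DataError("items and labels lengths differ")
        bad = set(self.labels) - set(self.classes)
        if bad:
            raise DataError(f"labels outside the class list: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.items)

    def class_counts(self) -> dict:
        return {c: self.labels.count(c) for c in self.classes}

    def subset(self, indices, role: str | None = None) -> "LabelledDataset":
        return LabelledDataset(
            items=[self.items[i] for i in indices],
            labels=[self.labels[i] for i in indices],
            classes=list(self.classes),
            role=role,
            masks=None if self.masks is None else [self.masks[i] for i in indices],
        )


@dataclass
class SplitResult:
    """Disjoint, exhaustive train/validation/test index sets."""

    train: list
    validation: list
    test: list
    seed: int
    test_frac: float
    val_frac_of_train: float


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_dataset(
    ds: LabelledDataset,
    test_frac: float = 0.2,
    val_frac_of_train: float = 0.2,
    seed: int = 0,
) -> SplitResult:
    """Stratified split: per class, round(n·test_frac) test images, then
    round-half-up of the remainder for validation, the rest for training.

    With 1000 images per class this reproduces the 640/160/200 bookkeeping
    exactly.
    """
    rng = np.random.default_rng(seed)
    labels = np.asarray(ds.labels)
    train: list[int] = []
    val: list[int] = []
    test: list[int] = []
    for cls in ds.classes:
        idx = np.flatnonzero(labels == cls)
        if idx.size == 0:
            continue
        if idx.size < 5:
            raise DataError(f"class {cls!r} has fewer than 5 samples ({idx.size})")
        idx = idx[rng.permutation(idx.size)]
        n_test = _round_half_up(idx.size * test_frac)
        rest = idx.size - n_test
        n_val = _round_half_up(rest * val_frac_of_train)
        test.extend(idx[:n_test].tolist())
        val.extend(idx[n_test : n_test + n_val].tolist())
        train.extend(idx[n_test + n_val :].tolist())
    return SplitResult(
        train=sorted(train),
        validation=sorted(val),
        test=sorted(test),
        seed=seed,
        test_frac=test_frac,
        val_frac_of_train=val_frac_of_train,
    )


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def _translate(img: np.ndarray, dr: int, dc: int) -> np.ndarray:
    shift = (dr, dc) if img.ndim == 2 else (dr, dc, 0)
    return ndimage.shift(img, shift, order=1, mode="nearest")


def _zoom_keep_size(img: np.ndarray, factor: float) -> np.ndarray:
    h, w = img.shape[:2]
    zoom = (factor, factor) if img.ndim == 2 else (factor, factor, 1)
    out = ndimage.zoom(img, zoom, order=1, mode="nearest")
    oh, ow = out.shape[:2]
    if oh >= h:
        r0 = (oh - h) // 2
        c0 = (ow - w) // 2
        return out[r0 : r0 + h, c0 : c0 + w]
    pad_r = h - oh
    pad_c = w - ow
    pads = [(pad_r // 2, pad_r - pad_r // 2), (pad_c // 2, pad_c - pad_c // 2)]
    if img.ndim == 3:
        pads.append((0, 0))
    return np.pad(out, pads, mode="edge")


def augment(ds: LabelledDataset, seed: int = 0) -> LabelledDataset:
    """Each training image yields itself plus 7 label-preserving transforms.

    The transforms are horizontal flip, vertical flip, rotations by
    90°/180°/270°, a seeded translation of up to 10% of the frame, and a
    seeded zoom in [0.9, 1.1].  Only the training split may be augmented.
    """
    if ds.role not in (None, "train"):
        raise DataError(f"augmentation applies to the training split, not {ds.role!r}")
    rng = np.random.default_rng(seed)
    items: list = []
    labels: list = []
    for img, lab in zip(ds.items, ds.labels):
        arr = np.asarray(img)
        h, w = arr.shape[:2]
        dr = int(rng.integers(-h // 10, h // 10 + 1))
        dc = int(rng.integers(-w // 10, w // 10 + 1))
        factor = float(rng.uniform(0.9, 1.1))
        variants = [
            arr,
            arr[:, ::-1].copy(),
            arr[::-1, :].copy(),
            np.rot90(arr, 1).copy(),
            np.rot90(arr, 2).copy(),
            np.rot90(arr, 3).copy(),
            _translate(arr, dr, dc),
            _zoom_keep_size(arr, factor),
        ]
        items.extend(variants)
        labels.extend([lab] * 8)
    return LabelledDataset(items=items, labels=labels, classes=list(ds.classes), role="train")


# ---------------------------------------------------------------------------
# Confusion matrix and metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """K×K counts; rows are actual classes, columns are predicted."""

    counts: np.ndarray
    classes: list

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion(actual, predicted, classes=None) -> ConfusionMatrix:
    """Tally an actual-by-predicted count matrix over the class list."""
    a = list(actual)
    p = list(predicted)
    if len(a) != len(p):
        raise DataError("actual and predicted lengths differ")
    if classes is None:
        classes = sorted(set(a) | set(p))
    index = {c: i for i, c in enumerate(classes)}
    unknown = (set(a) | set(p)) - set(classes)
    if unknown:
        raise DataError(f"labels outside the class list: {sorted(unknown)}")
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for ai, pi in zip(a, p):
        counts[index[ai], index[pi]] += 1
    return ConfusionMatrix(counts=counts, classes=list(classes))


def _rate(numer: float, denom: float) -> float:
    """Percentage rate with the 0/0 → 100 convention for empty event sets."""
    if denom == 0:
        return 100.0
    return 100.0 * numer / denom


@dataclass
class MetricsReport:
    """Per-class and macro one-vs-rest rates, all in percent."""

    per_class: dict
    macro: dict
    overall_accuracy: float


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest accuracy, precision, sensitivity and specificity per class.

    Macro values are unweighted class means; the overall accuracy is
    trace/total × 100.  A 0/0 rate (empty event set) is defined as 100.
    """
    counts = cm.counts
    total = counts.sum()
    if total < 1:
        raise ParameterError("confusion matrix is empty")
    per_class: dict = {}
    for i, cls in enumerate(cm.classes):
        tp = counts[i, i]
        fn = counts[i, :].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        per_class[cls] = {
            "accuracy": _rate(tp + tn, total),
            "precision": _rate(tp, tp + fp),
            "sensitivity": _rate(tp, tp + fn),
            "specificity": _rate(tn, tn + fp),
        }
    macro = {
        key: float(np.mean([per_class[c][key] for c in cm.classes]))
        for key in ("accuracy", "precision", "sensitivity", "specificity")
    }
    overall = 100.0 * np.trace(counts) / total
    return MetricsReport(per_class=per_class, macro=macro, overall_accuracy=float(overall))


def overall_accuracy(per_class_acc, class_sizes) -> float:
    """Size-weighted mean of per-class accuracies, rounded to 1 decimal."""
    acc = np.asarray(per_class_acc, dtype=np.float64)
    sizes = np.asarray(class_sizes, dtype=np.float64)
    if acc.shape != sizes.shape:
        raise ParameterError("per-class accuracies and sizes differ in length")
    if np.any(sizes <= 0):
        raise ParameterError("class sizes must be positive")
    return round(float((acc * sizes).sum() / sizes.sum()), 1)


def roc_auc(scores: np.ndarray, actual, classes) -> tuple[dict, float]:
    """One-vs-rest ROC area per class (×100) and the macro mean.

    ``scores`` is an (n, K) table of per-class probabilities/scores in the
    order of ``classes``.  A class with no positives or no negatives in the
    ground truth has no defined ROC and raises.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(actual)
    if s.shape[0] != y.shape[0]:
        raise DataError("score rows and labels differ in length")
    per_class: dict = {}
    for k, cls in enumerate(classes):
        pos = y == cls
        if pos.all() or not pos.any():
            raise ParameterError(
                f"AUC undefined for class {cls!r}: needs positives and negatives"
            )
        fpr, tpr, _ = roc_curve(pos.astype(int), s[:, k])
        per_class[cls] = 100.0 * float(_auc(fpr, tpr))
    macro = float(np.mean(list(per_class.values())))
    return per_class, macro


def mask_scores(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Pixel-level accuracy, precision, recall and Dice, in percent."""
    p = np.asarray(pred).astype(bool)
    t = np.asarray(truth).astype(bool)
    if p.shape != t.shape:
        raise ParameterError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = float(np.sum(p & t))
    tn = float(np.sum(~p & ~t))
    fp = float(np.sum(p & ~t))
    fn = float(np.sum(~p & t))
    return {
        "accuracy": _rate(tp + tn, tp + tn + fp + fn),
        "precision": _rate(tp, tp + fp),
        "recall": _rate(tp, tp + fn),
        "dice": _rate(2 * tp, 2 * tp + fp + fn),
    }
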