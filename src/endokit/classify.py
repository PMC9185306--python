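"""Shallow classifiers over fused feature vectors.

Two classifier families are provided:

* a single-hidden-layer feed-forward network (default 30 hidden units,
  ReLU hidden activation, softmax output) trained by full-batch gradient
  descent on the cross-entropy objective, with early stopping on a held-out
  validation split and the mean squared error logged alongside;
* a multiclass soft-margin SVM (one-vs-one, linear kernel, C = 1.0,
  standardized inputs) from scikit-learn.

Both trainers are deterministic given their seed.  Features are
standardized internally (train-split statistics); models remember the
scaling so prediction takes raw features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ContractError, DataError, ParameterError

__all__ = [
    "softmax",
    "relu",
    "mse",
    "TrainConfig",
    "MLPModel",
    "train_mlp",
    "train_svm",
    "predict",
    "save_model",
    "load_model",
]


def softmax(logits: np.ndarray) -> np.ndarray:
    """Shift-stable softmax: y_i = exp(x_i) / Σ_j exp(x_j).

    Accepts a vector or a matrix of row-wise logits.
    """
    x = np.asarray(logits, dtype=np.float64)
    if x.size == 0:
        raise ParameterError("softmax requires at least one logit")
    shifted = x - x.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def relu(x: np.ndarray) -> np.ndarray:
    """Element-wise max(0, x)."""
    return np.maximum(0.0, np.asarray(x, dtype=np.float64))


def mse(actual: np.ndarray, predicted: np.ndarray) -> float:
    """Mean squared error (1/n)·Σ (a_i − p_i)²."""
    a = np.asarray(actual, dtype=np.float64).ravel()
    p = np.asarray(predicted, dtype=np.float64).ravel()
    if a.size != p.size:
        raise ParameterError(
            f"length mismatch: actual has {a.size}, predicted has {p.size}"
        )
    if a.size == 0:
        raise ParameterError("mse requires at least one element")
    return float(np.mean((a - p) ** 2))


@dataclass
class TrainConfig:
    """Hyperparameters of the feed-forward trainer."""

    hidden: int = 30
    max_epochs: int = 500
    learning_rate: float = 0.5
    patience: int = 25
    seed: int = 0
    l2: float = 1e-4

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ParameterError("max_epochs must be ≥ 1")
        if self.patience < 1:
            raise ParameterError("patience must be ≥ 1")


@dataclass
class MLPModel:
    """Trained one-hidden-layer network plus the fitted input scaling."""

    classes: list
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    seed: int = 0
    train_log: dict = field(default_factory=dict)

    @property
    def input_width(self) -> int:
        return self.w1.shape[0]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Row-wise class probabilities for raw (unscaled) features."""
        z = (np.asarray(x, np.float64) - self.mean) / self.scale
        hidden = relu(z @ self.w1 + self.b1)
        return softmax(hidden @ self.w2 + self.b2)


def _check_training_inputs(features: np.ndarray, labels) -> tuple[np.ndarray, np.ndarray, list]:
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if x.ndim != 2:
        raise DataError("features must be a 2-D table (rows = samples)")
    if y.shape[0] != x.shape[0]:
        raise DataError(
            f"labels length {y.shape[0]} does not match {x.shape[0]} feature rows"
        )
    if not np.all(np.isfinite(x)):
        raise DataError("features contain non-finite values")
    classes = sorted(np.unique(y).tolist())
    if len(classes) < 2:
        raise DataError("training requires at least two classes")
    return x, y, classes


def train_mlp(
    features: np.ndarray,
    labels,
    config: TrainConfig | None = None,
    val_features: np.ndarray | None = None,
    val_labels=None,
) -> MLPModel:
    """Train the feed-forward network with validation-based early stopping.

    When a validation split is supplied, the validation cross-entropy is
    monitored every epoch; training stops after ``patience`` epochs without
    improvement and the weights of the best epoch are kept.  Without a
    validation split the full ``max_epochs`` run on the training loss.
    """
    cfg = config or TrainConfig()
    x, y, classes = _check_training_inputs(features, labels)
    class_index = {c: k for k, c in enumerate(classes)}
    y_idx = np.array([class_index[v] for v in y])
    n, d = x.shape
    k = len(classes)
    onehot = np.eye(k)[y_idx]

    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale[scale < 1e-8] = 1.0
    xs = (x - mean) / scale

    if val_features is not None:
        xv = (np.asarray(val_features, np.float64) - mean) / scale
        yv_idx = np.array([class_index[v] for v in np.asarray(val_labels)])
    else:
        xv = None

    rng = np.random.default_rng(cfg.seed)
    w1 = rng.standard_normal((d, cfg.hidden)) * np.sqrt(2.0 / d)
    b1 = np.zeros(cfg.hidden)
    w2 = rng.standard_normal((cfg.hidden, k)) * np.sqrt(2.0 / cfg.hidden)
    b2 = np.zeros(k)

    best = None
    best_val = np.inf
    best_epoch = -1
    stall = 0
    log: dict = {"train_loss": [], "train_mse": [], "val_loss": []}

    for epoch in range(cfg.max_epochs):
        h_pre = xs @ w1 + b1
        h = relu(h_pre)
        probs = softmax(h @ w2 + b2)
        eps = 1e-12
        loss = float(-np.mean(np.log(probs[np.arange(n), y_idx] + eps)))
        log["train_loss"].append(loss)
        log["train_mse"].append(mse(onehot, probs))

        grad_out = (probs - onehot) / n
        gw2 = h.T @ grad_out + cfg.l2 * w2
        gb2 = grad_out.sum(axis=0)
        grad_h = (grad_out @ w2.T) * (h_pre > 0)
        gw1 = xs.T @ grad_h + cfg.l2 * w1
        gb1 = grad_h.sum(axis=0)
        w1 -= cfg.learning_rate * gw1
        b1 -= cfg.learning_rate * gb1
        w2 -= cfg.learning_rate * gw2
        b2 -= cfg.learning_rate * gb2

        if xv is not None:
            pv = softmax(relu(xv @ w1 + b1) @ w2 + b2)
            vloss = float(-np.mean(np.log(pv[np.arange(len(yv_idx)), yv_idx] + eps)))
            log["val_loss"].append(vloss)
            if vloss < best_val:
                best_val = vloss
                best = (w1.copy(), b1.copy(), w2.copy(), b2.copy())
                best_epoch = epoch
                stall = 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break

    if best is not None:
        w1, b1, w2, b2 = best
        log["best_epoch"] = best_epoch
        log["best_val_loss"] = best_val
    return MLPModel(
        classes=classes,
        w1=w1,
        b1=b1,
        w2=w2,
        b2=b2,
        mean=mean,
        scale=scale,
        seed=cfg.seed,
        train_log=log,
    )


def train_svm(features: np.ndarray, labels, c: float = 1.0, seed: int = 0) -> Pipeline:
    """Multiclass linear soft-margin SVM (one-vs-one) on standardized inputs."""
    x, y, _ = _check_training_inputs(features, labels)
    model = Pipeline(
        [
            ("scale", StandardScaler()),
            ("svm", SVC(kernel="linear", C=c, decision_function_shape="ovo",
                        random_state=seed)),
        ]
    )
    model.fit(x, y)
    return model


def predict(model, features: np.ndarray):
    """Predicted labels, plus a per-class probability/score table for MLPs.

    Returns ``(labels, probs)``; ``probs`` is None for SVM models.
    An empty feature table yields empty predictions.
    """
    x = np.asarray(features, dtype=np.float64)
    if x.ndim == 1:
        x = x.reshape(1, -1) if x.size else x.reshape(0, 0)
    if isinstance(model, MLPModel):
        if x.shape[0] == 0:
            return np.array([], dtype=object), np.zeros((0, len(model.classes)))
        if x.shape[1] != model.input_width:
            raise ContractError(
                f"model expects width {model.input_width}, got {x.shape[1]}"
            )
        probs = model.forward(x)
        labels = np.array([model.classes[i] for i in probs.argmax(axis=1)])
        return labels, probs
    if x.shape[0] == 0:
        return np.array([], dtype=object), None
    expected = model.named_steps["scale"].mean_.shape[0]
    if x.shape[1] != expected:
        raise ContractError(f"model expects width {expected}, got {x.shape[1]}")
    return model.predict(x), None


def save_model(model: MLPModel, path: str | Path) -> None:
    """Serialize an MLP to a portable .npz archive with a JSON manifest."""
    path = Path(path)
    manifest = json.dumps({"classes": model.classes, "seed": model.seed})
    np.savez(
        path,
        manifest=np.frombuffer(manifest.encode(), dtype=np.uint8),
        w1=model.w1,
        b1=model.b1,
        w2=model.w2,
        b2=model.b2,
        mean=model.mean,
        scale=model.scale,
    )


def load_model(path: str | Path) -> MLPModel:
    data = np.load(Path(path).with_suffix(".npz") if not str(path).endswith(".npz") else path)
    manifest = json.loads(bytes(data["manifest"]).decode())
    return MLPModel(
        classes=manifest["classes"],
        w1=data["w1"],
        b1=data["b1"],
        w2=data["w2"],
        b2=data["b2"],
        mean=data["mean"],
        scale=data["scale"],
        seed=manifest["seed"],
    )
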