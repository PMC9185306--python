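"""End-to-end pipeline glue: enhancement → features → classifier → metrics."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import TrainConfig, predict, train_mlp
from .enhance import enhance
from .evaluate import (
    KVASIR_CLASSES,
    LabelledDataset,
    confusion,
    metrics,
    split_dataset,
)
from .features import (
    FeatureVector,
    deep_extract,
    fch_features,
    fuse,
    fuse_deep,
    glcm_features,
    lbp_features,
)
from .synthdata import generate_dataset

__all__ = [
    "extract_handcrafted",
    "extract_hybrid",
    "features_table",
    "run_phantom_benchmark",
]


def extract_handcrafted(
    rgb: np.ndarray, mask: np.ndarray | None = None
) -> FeatureVector:
    """The 232-wide handcrafted vector for one frame.

    Texture descriptors (LBP, GLCM) are computed from the enhanced
    grayscale plane; the color histogram (FCH) from the original RGB
    pixels.  With a mask, descriptors use masked pixels only; without one,
    the whole frame.
    """
    enhanced = enhance(rgb).pixels
    return fuse(
        [
            lbp_features(enhanced, mask=mask),
            glcm_features(enhanced, mask=mask),
            fch_features(rgb, mask=mask),
        ]
    )


def extract_hybrid(
    rgb: np.ndarray, mask: np.ndarray | None = None, extractor=None
) -> FeatureVector:
    """Deep embedding fused with the 232 handcrafted features (4328 default)."""
    return fuse_deep(deep_extract(rgb, extractor), extract_handcrafted(rgb, mask))


def features_table(
    ds: LabelledDataset, use_masks: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-image handcrafted vectors into (X, y) arrays."""
    rows = []
    for i, img in enumerate(ds.items):
        mask = ds.masks[i] if (use_masks and ds.masks is not None) else None
        rows.append(extract_handcrafted(np.asarray(img), mask=mask).values)
    return np.vstack(rows), np.asarray(ds.labels)


def features_dataframe(ds: LabelledDataset, use_masks: bool = False) -> pd.DataFrame:
    """Feature table as a DataFrame: `<block>_<index>` columns plus label."""
    x, y = features_table(ds, use_masks=use_masks)
    sample = extract_handcrafted(np.asarray(ds.items[0]))
    cols: list[str] = []
    counters: dict[str, int] = {}
    for lab in sample.block_labels:
        counters[lab] = counters.get(lab, 0)
        cols.append(f"{lab}_{counters[lab]}")
        counters[lab] += 1
    df = pd.DataFrame(x, columns=cols)
    df.insert(0, "image_id", np.arange(len(y)))
    df["label"] = y
    return df


def run_phantom_benchmark(
    n_per_class: int = 100, seed: int = 0, size: int = 128
) -> dict:
    """Full study on the phantom dataset: generate, split, train, score.

    Generates the balanced 5-class phantom set, extracts the 232-feature
    handcrafted vector per frame, splits it stratified (train/val/test),
    trains the feed-forward network with early stopping on the validation
    split, and reports test accuracy with the full metrics breakdown.
    """
    ds = generate_dataset(n_per_class, seed=seed, size=size)
    x, y = features_table(ds)
    split = split_dataset(ds, seed=seed)
    model = train_mlp(
        x[split.train],
        y[split.train],
        TrainConfig(seed=seed),
        val_features=x[split.validation],
        val_labels=y[split.validation],
    )
    pred, probs = predict(model, x[split.test])
    cm = confusion(y[split.test], pred, classes=KVASIR_CLASSES)
    report = metrics(cm)
    return {
        "model": model,
        "confusion": cm,
        "report": report,
        "test_accuracy": float(np.mean(pred == y[split.test])),
        "probs": probs,
        "test_labels": y[split.test],
        "split": split,
    }
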