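"""Deterministic endoscopy-like phantom generator.

The generator emulates the structure of a 5-class lower-GI endoscopy
dataset so the rest of the pipeline is testable without any download:

* **dyed-lifted-polyps** — warm mucosa with an elliptical lifted blob under
  a blue-green dye tint;
* **normal-cecum** — pale pink mucosa with low-frequency texture, no lesion;
* **normal-pylorus** — darker red mucosa with a concentric ring pattern,
  no lesion;
* **polyps** — mucosa with a bright protruding elliptical blob carrying a
  small specular highlight;
* **ulcerative-colitis** — mucosa with a diffusely reddened, granular
  region.

Classes draw base colors from disjoint intervals and lesion interiors
differ from the surrounding mucosa by at least 60 gray levels before noise,
so class separability (and lesion/background contrast for segmentation)
holds by construction rather than by tuning.  Lesions never touch the image
border.  Every image is a deterministic function of its spec and seed.

The phantoms are parametric cartoons: they reproduce class-wise color and
texture statistics and lesion geometry, not the optics of a real endoscope
(no motion blur, fluids, or picture-in-picture navigation overlays beyond a
flat tint patch).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import ParameterError
from .evaluate import KVASIR_CLASSES, LabelledDataset

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "generate_dataset",
    "generate_disc",
    "DiscPhantom",
]

# Per-class base mucosa color (R, G, B) and texture frequency (cycles/frame).
_CLASS_STYLE = {
    "dyed-lifted-polyps": {"base": (220.0, 140.0, 120.0), "freq": 3.0},
    "normal-cecum": {"base": (235.0, 175.0, 140.0), "freq": 2.0},
    "normal-pylorus": {"base": (175.0, 88.0, 88.0), "freq": 8.0},
    "polyps": {"base": (200.0, 130.0, 100.0), "freq": 4.0},
    "ulcerative-colitis": {"base": (195.0, 125.0, 105.0), "freq": 5.0},
}

# Lesion fill colors; gray-level contrast to the class base is ≥ 60 pre-noise.
_LESION_COLOR = {
    "dyed-lifted-polyps": (30.0, 110.0, 140.0),   # dye tint, gray ≈ 93 vs 160
    "polyps": (252.0, 206.0, 178.0),              # bright blob, gray ≈ 212 vs 143
    "ulcerative-colitis": (150.0, 28.0, 28.0),    # deep red, gray ≈ 69 vs 142
}


@dataclass
class PhantomSpec:
    """Recipe for one phantom frame.

    ``lesion_center``/``lesion_axes``/``lesion_angle`` may be pinned for
    analytic tests; left as None they are drawn deterministically from the
    seed within ranges that keep the lesion clear of the border.
    """

    klass: str
    size: int = 128
    noise_sigma: float = 6.0
    seed: int = 0
    lesion_center: tuple[float, float] | None = None
    lesion_axes: tuple[float, float] | None = None
    lesion_angle: float | None = None

    def __post_init__(self) -> None:
        if self.klass not in _CLASS_STYLE:
            raise ParameterError(
                f"unknown class {self.klass!r}; expected one of {KVASIR_CLASSES}"
            )
        if self.size < 64:
            raise ParameterError(f"phantom size must be ≥ 64, got {self.size}")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be ≥ 0")


def _ellipse_mask(
    size: int,
    center: tuple[float, float],
    axes: tuple[float, float],
    angle: float,
) -> np.ndarray:
    rows, cols = np.mgrid[0:size, 0:size].astype(np.float64)
    dr = rows - center[0]
    dc = cols - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray | None]:
    """Render one phantom; returns (RGB uint8 image, lesion mask or None)."""
    rng = np.random.default_rng(spec.seed)
    size = spec.size
    style = _CLASS_STYLE[spec.klass]
    base = np.array(style["base"])
    # Whole-frame luminance jitter preserves lesion/background contrast.
    jitter = rng.uniform(-8.0, 8.0)

    rows, cols = np.mgrid[0:size, 0:size].astype(np.float64)
    cy = cx = (size - 1) / 2.0
    radial = np.hypot(rows - cy, cols - cx) / (size / 2.0)

    img = np.empty((size, size, 3), dtype=np.float64)
    img[:] = base + jitter

    freq = style["freq"]
    if spec.klass == "normal-pylorus":
        texture = 9.0 * np.sin(2.0 * np.pi * freq * radial)
    else:
        phase = rng.uniform(0, 2 * np.pi)
        texture = 7.0 * np.sin(2.0 * np.pi * freq * rows / size + phase) * np.cos(
            2.0 * np.pi * freq * cols / size
        )
    img += texture[..., None]

    mask: np.ndarray | None = None
    if spec.klass in _LESION_COLOR:
        center = spec.lesion_center
        if center is None:
            margin = 0.08 * size
            center = (
                cy + rng.uniform(-margin, margin),
                cx + rng.uniform(-margin, margin),
            )
        axes = spec.lesion_axes
        if axes is None:
            axes = (
                rng.uniform(0.09, 0.16) * size,
                rng.uniform(0.09, 0.16) * size,
            )
        angle = spec.lesion_angle
        if angle is None:
            angle = rng.uniform(0, np.pi)
        mask = _ellipse_mask(size, center, axes, angle)
        lesion = np.array(_LESION_COLOR[spec.klass]) + jitter
        img[mask] = lesion + texture[mask, None] * 0.3
        if spec.klass == "polyps":
            spot = _ellipse_mask(
                size,
                (center[0] - 0.3 * axes[0], center[1] - 0.3 * axes[1]),
                (max(2.0, 0.18 * axes[0]), max(2.0, 0.18 * axes[1])),
                angle,
            )
            img[spot & mask] = 255.0
        if spec.klass == "ulcerative-colitis":
            granular = rng.normal(0.0, 14.0, size=(int(mask.sum()), 1))
            img[mask] += granular

    # Mild vignette, strongest at the frame corners.
    strength = rng.uniform(0.10, 0.25)
    img *= (1.0 - strength * np.clip(radial, 0, np.sqrt(2)) ** 2 / 2.0)[..., None]

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), mask


def _child_seed(master: int, class_index: int, item_index: int) -> int:
    ss = np.random.SeedSequence([int(master), class_index, item_index])
    return int(ss.generate_state(1)[0] % (2**31))


def generate_dataset(
    n_per_class: int, seed: int = 0, size: int = 128, noise_sigma: float = 6.0
) -> LabelledDataset:
    """Balanced 5-class phantom dataset with per-image derived seeds.

    Returns a :class:`LabelledDataset` whose ``masks`` list holds the
    ground-truth lesion mask for lesion classes and None for normal ones.
    """
    if n_per_class < 10:
        raise ParameterError(f"n_per_class must be ≥ 10, got {n_per_class}")
    items: list = []
    labels: list = []
    masks: list = []
    for ci, cls in enumerate(KVASIR_CLASSES):
        for j in range(n_per_class):
            spec = PhantomSpec(
                klass=cls,
                size=size,
                noise_sigma=noise_sigma,
                seed=_child_seed(seed, ci, j),
            )
            img, mask = generate_phantom(spec)
            items.append(img)
            labels.append(cls)
            masks.append(mask)
    return LabelledDataset(items=items, labels=labels, masks=masks)


class DiscPhantom(NamedTuple):
    image: np.ndarray
    mask: np.ndarray
    degenerate: bool


def generate_disc(
    size: int = 128,
    radius: float = 30.0,
    fg: float = 200.0,
    bg: float = 50.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> DiscPhantom:
    """Centered disc of value ``fg`` on ``bg`` plus seeded Gaussian noise.

    The exact disc indicator is returned as ground truth.  A contrast below
    4σ (where the segmentation property suite no longer guarantees overlap)
    triggers a warning, and zero contrast sets the ``degenerate`` flag.
    """
    if radius >= size / 2:
        raise ParameterError("radius must be smaller than half the image size")
    degenerate = fg == bg
    if noise_sigma > 0 and abs(fg - bg) < 4 * noise_sigma:
        warnings.warn(
            f"contrast |fg-bg|={abs(fg - bg)} below 4σ={4 * noise_sigma}",
            stacklevel=2,
        )
    if degenerate:
        warnings.warn("fg equals bg: zero-contrast disc phantom", stacklevel=2)
    rows, cols = np.mgrid[0:size, 0:size].astype(np.float64)
    c = (size - 1) / 2.0
    mask = np.hypot(rows - c, cols - c) <= radius
    img = np.where(mask, float(fg), float(bg))
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    return DiscPhantom(image=img, mask=mask, degenerate=degenerate)
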