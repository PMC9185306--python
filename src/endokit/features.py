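"""Handcrafted texture/color descriptors and feature fusion.

Three descriptor blocks are computed per region of interest and concatenated
into one vector per image:

* **LBP** — circular local binary patterns (P=8 neighbors, radius R=1,
  bilinear sampling).  Per-pixel codes are histogrammed into a configurable
  number of equal-width bins over [0, 2^P − 1]; the published descriptor
  width of 203 bins is the default, a 256-bin exact mode is available.
* **GLCM** — symmetric gray-level co-occurrence matrices at four offsets
  (0° with d=1, 45° with d=√2, 90° with d=1, 135° with d=√2) after uniform
  quantization, summarized by the classical 13 Haralick statistics and
  averaged over the four offsets.
* **FCH** — a fuzzy color histogram over 16 fixed bin centers on a
  4(R)×2(G)×2(B) lattice of channel midpoints; each pixel spreads graded
  membership ∝ 1/(d² + τ) over all centers (a crisp nearest-center mode is
  also provided).

Fusing LBP(203) + GLCM(13) + FCH(16) yields the 232-wide handcrafted vector;
prepending a deep embedding (default width 4096) yields the 4328-wide hybrid
vector.  When a binary mask is supplied, descriptors are computed from the
masked pixels only; otherwise the whole frame is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, ImageFormatError, ParameterError

__all__ = [
    "FeatureVector",
    "lbp_codes",
    "lbp_features",
    "glcm_table",
    "haralick_features",
    "glcm_features",
    "fch_features",
    "fch_bin_centers",
    "fuse",
    "RandomProjectionExtractor",
    "deep_extract",
    "fuse_deep",
]


@dataclass
class FeatureVector:
    """Ordered real values with a per-value block-of-origin tag."""

    values: np.ndarray
    block_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ParameterError("feature values must form a 1-D vector")
        if len(self.block_labels) != self.values.size:
            raise ParameterError("one block label per value is required")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("feature values must be finite")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def blocks(self) -> list[str]:
        """Distinct block tags in order of first appearance."""
        seen: list[str] = []
        for lab in self.block_labels:
            if lab not in seen:
                seen.append(lab)
        return seen


def _as_gray_roi(roi: np.ndarray) -> np.ndarray:
    arr = np.asarray(roi, dtype=np.float64)
    if arr.ndim != 2:
        raise ImageFormatError(f"expected a 2-D gray ROI, got shape {arr.shape}")
    return arr


def _check_mask(arr: np.ndarray, mask: np.ndarray | None) -> np.ndarray:
    if mask is None:
        return np.ones(arr.shape[:2], dtype=bool)
    m = np.asarray(mask).astype(bool)
    if m.shape != arr.shape[:2]:
        raise ImageFormatError("mask shape differs from ROI shape")
    if m.sum() < 16:
        raise ImageFormatError("ROI must contain at least 16 foreground pixels")
    return m


# ---------------------------------------------------------------------------
# LBP
# ---------------------------------------------------------------------------

def lbp_codes(gray: np.ndarray, neighbors: int = 8, radius: float = 1.0) -> np.ndarray:
    """Per-pixel circular LBP codes with bilinear neighbor sampling.

    For interior pixel (r, c), neighbor p sits at angle 2πp/P on a circle of
    the given radius (row offset −R·sin, column offset +R·cos) and the code is
    Σ_p s(g_p − g_c)·2^p with s(x) = 1 for x ≥ 0.  Border pixels within R of
    the edge get code 0 and are excluded by callers.
    """
    img = _as_gray_roi(gray)
    h, w = img.shape
    pad = int(np.ceil(radius))
    if h < 2 * pad + 1 or w < 2 * pad + 1:
        raise ImageFormatError(
            f"ROI of shape {img.shape} too small for radius {radius}"
        )
    codes = np.zeros((h, w), dtype=np.int64)
    rr, cc = np.mgrid[pad : h - pad, pad : w - pad]
    center = img[pad : h - pad, pad : w - pad]
    for p in range(neighbors):
        angle = 2.0 * np.pi * p / neighbors
        dr = -radius * np.sin(angle)
        dc = radius * np.cos(angle)
        # snap near-integer offsets to avoid interpolation noise on the axes
        if abs(dr - round(dr)) < 1e-9:
            dr = round(dr)
        if abs(dc - round(dc)) < 1e-9:
            dc = round(dc)
        r = rr + dr
        c = cc + dc
        r0 = np.floor(r).astype(int)
        c0 = np.floor(c).astype(int)
        fr = r - r0
        fc = c - c0
        r1 = np.clip(r0 + 1, 0, h - 1)
        c1 = np.clip(c0 + 1, 0, w - 1)
        r0 = np.clip(r0, 0, h - 1)
        c0 = np.clip(c0, 0, w - 1)
        sample = (
            img[r0, c0] * (1 - fr) * (1 - fc)
            + img[r0, c1] * (1 - fr) * fc
            + img[r1, c0] * fr * (1 - fc)
            + img[r1, c1] * fr * fc
        )
        codes[pad : h - pad, pad : w - pad] += ((sample - center) >= 0).astype(
            np.int64
        ) << p
    return codes


def lbp_features(
    roi: np.ndarray,
    mask: np.ndarray | None = None,
    neighbors: int = 8,
    radius: float = 1.0,
    bins: int = 203,
) -> FeatureVector:
    """Normalized LBP-code histogram over the masked interior pixels."""
    if neighbors != 8:
        raise ParameterError("only P=8 circular neighborhoods are supported")
    if radius < 1:
        raise ParameterError(f"radius must be ≥ 1, got {radius}")
    if bins < 2:
        raise ParameterError(f"bins must be ≥ 2, got {bins}")
    img = _as_gray_roi(roi)
    m = _check_mask(img, mask)
    codes = lbp_codes(img, neighbors=neighbors, radius=radius)
    pad = int(np.ceil(radius))
    interior = np.zeros_like(m)
    interior[pad:-pad, pad:-pad] = m[pad:-pad, pad:-pad]
    selected = codes[interior]
    if selected.size == 0:
        raise ImageFormatError("no interior masked pixels for LBP")
    top = float(2**neighbors - 1)
    hist, _ = np.histogram(selected, bins=bins, range=(0.0, top))
    hist = hist.astype(np.float64) / hist.sum()
    return FeatureVector(values=hist, block_labels=["lbp"] * bins)


# ---------------------------------------------------------------------------
# GLCM / Haralick
# ---------------------------------------------------------------------------

#: (row, col) steps pairing d=1 with the axial angles and d=√2 with diagonals.
GLCM_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

HARALICK_NAMES = [
    "energy",
    "contrast",
    "correlation",
    "variance",
    "inverse_difference_moment",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
]


def quantize(gray: np.ndarray, n_levels: int) -> np.ndarray:
    """Uniform quantization of the ROI's own intensity range to n_levels."""
    img = _as_gray_roi(gray)
    lo = img.min()
    hi = img.max()
    if hi == lo:
        return np.zeros(img.shape, dtype=np.intp)
    levels = np.floor((img - lo) / (hi - lo) * n_levels).astype(np.intp)
    return np.clip(levels, 0, n_levels - 1)


def glcm_table(
    levels: np.ndarray,
    offset: tuple[int, int],
    n_levels: int,
    mask: np.ndarray | None = None,
    symmetric: bool = True,
) -> np.ndarray:
    """Normalized co-occurrence table for one (Δrow, Δcol) offset.

    Only pairs whose both endpoints are masked contribute.  With
    ``symmetric`` the transposed pairs are accumulated too, which is the
    convention assumed by the Haralick statistics here.
    """
    lv = np.asarray(levels)
    m = np.ones(lv.shape, bool) if mask is None else np.asarray(mask, bool)
    dr, dc = offset
    h, w = lv.shape
    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    a = lv[r0s:r0e, c0s:c0e]
    b = lv[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    valid = m[r0s:r0e, c0s:c0e] & m[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    counts = np.zeros((n_levels, n_levels), dtype=np.float64)
    np.add.at(counts, (a[valid], b[valid]), 1.0)
    if symmetric:
        counts = counts + counts.T
    total = counts.sum()
    if total > 0:
        counts /= total
    return counts


def haralick_features(p: np.ndarray) -> np.ndarray:
    """The classical 13 Haralick statistics of one normalized GLCM.

    Natural logarithms throughout; 0·log 0 ≡ 0; correlation-type features
    are defined as 0 when a marginal variance vanishes.
    """
    n = p.shape[0]
    i = np.arange(n, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    var_y = float(((i - mu_y) ** 2 * py).sum())

    def ent(q: np.ndarray) -> float:
        q = q[q > 0]
        return float(-(q * np.log(q)).sum())

    # p_{x+y}(k), k = 0..2n−2 and p_{x−y}(k), k = 0..n−1 (0-based levels)
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (ii + jj).astype(int).ravel(), p.ravel())
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(ii - jj).astype(int).ravel(), p.ravel())
    k_sum = np.arange(2 * n - 1, dtype=np.float64)
    k_diff = np.arange(n, dtype=np.float64)

    energy = float((p**2).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    if var_x > 0 and var_y > 0:
        correlation = float(
            ((ii - mu_x) * (jj - mu_y) * p).sum() / np.sqrt(var_x * var_y)
        )
    else:
        correlation = 0.0
    variance = float(((ii - mu_x) ** 2 * p).sum())
    idm = float((p / (1.0 + (ii - jj) ** 2)).sum())
    sum_average = float((k_sum * p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    sum_entropy = ent(p_sum)
    entropy = ent(p)
    diff_mean = float((k_diff * p_diff).sum())
    difference_variance = float(((k_diff - diff_mean) ** 2 * p_diff).sum())
    difference_entropy = ent(p_diff)
    hx = ent(px)
    hy = ent(py)
    hxy = entropy
    pxpy = np.outer(px, py)
    nz = (p > 0) & (pxpy > 0)
    hxy1 = float(-(p[nz] * np.log(pxpy[nz])).sum())
    nz2 = pxpy > 0
    hxy2 = float(-(pxpy[nz2] * np.log(pxpy[nz2])).sum())
    denom = max(hx, hy)
    imc1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    return np.array(
        [
            energy,
            contrast,
            correlation,
            variance,
            idm,
            sum_average,
            sum_variance,
            sum_entropy,
            entropy,
            difference_variance,
            difference_entropy,
            imc1,
            imc2,
        ]
    )


def glcm_features(
    roi: np.ndarray,
    mask: np.ndarray | None = None,
    n_levels: int = 32,
) -> FeatureVector:
    """13 Haralick statistics averaged over the four canonical offsets."""
    img = _as_gray_roi(roi)
    m = _check_mask(img, mask)
    levels = quantize(img, n_levels)
    per_offset = []
    for off in GLCM_OFFSETS:
        table = glcm_table(levels, off, n_levels, mask=m)
        per_offset.append(haralick_features(table))
    values = np.mean(per_offset, axis=0)
    return FeatureVector(values=values, block_labels=["glcm"] * len(HARALICK_NAMES))


# ---------------------------------------------------------------------------
# FCH
# ---------------------------------------------------------------------------

def fch_bin_centers(bins: int = 16) -> np.ndarray:
    """Fixed color-bin centers: channel midpoints of a 4(R)×2(G)×2(B) lattice."""
    if bins != 16:
        raise ParameterError("only the 16-bin 4×2×2 lattice is supported")
    r_centers = (np.arange(4) + 0.5) * (255.0 / 4)
    g_centers = (np.arange(2) + 0.5) * (255.0 / 2)
    b_centers = (np.arange(2) + 0.5) * (255.0 / 2)
    grid = np.stack(
        np.meshgrid(r_centers, g_centers, b_centers, indexing="ij"), axis=-1
    )
    return grid.reshape(-1, 3)


def fch_features(
    roi: np.ndarray,
    mask: np.ndarray | None = None,
    bins: int = 16,
    mode: str = "fuzzy",
    tau: float = 1.0,
) -> FeatureVector:
    """Fuzzy (or crisp) color histogram over the fixed 16-center lattice.

    Fuzzy mode spreads each pixel over all centers with membership
    ∝ 1/(d² + τ) (τ > 0 guards the zero-distance case); crisp mode assigns
    each pixel wholly to its nearest center.  The histogram sums to 1.
    """
    arr = np.asarray(roi, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ImageFormatError("FCH requires an RGB ROI (H×W×3)")
    if mode not in ("fuzzy", "crisp"):
        raise ParameterError(f"mode must be 'fuzzy' or 'crisp', got {mode!r}")
    m = _check_mask(arr, mask)
    centers = fch_bin_centers(bins)
    pixels = arr[m]  # (n, 3)
    d2 = ((pixels[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    if mode == "crisp":
        nearest = d2.argmin(axis=1)
        hist = np.bincount(nearest, minlength=bins).astype(np.float64)
    else:
        memb = 1.0 / (d2 + tau)
        memb /= memb.sum(axis=1, keepdims=True)
        hist = memb.sum(axis=0)
    hist /= hist.sum()
    return FeatureVector(values=hist, block_labels=["fch"] * bins)


# ---------------------------------------------------------------------------
# Fusion and deep embeddings
# ---------------------------------------------------------------------------

def fuse(blocks: list[FeatureVector]) -> FeatureVector:
    """Concatenate descriptor blocks in the given order, keeping labels."""
    if not blocks:
        raise ParameterError("fuse requires at least one feature block")
    values = np.concatenate([b.values for b in blocks])
    labels: list[str] = []
    for b in blocks:
        labels.extend(b.block_labels)
    return FeatureVector(values=values, block_labels=labels)


class RandomProjectionExtractor:
    """Seeded random linear projection of a downsampled frame.

    A stand-in embedding used to exercise the deep-feature plumbing and the
    4096/4328 vector shapes: the image is block-averaged to a small grid and
    projected through a fixed Gaussian matrix drawn once from the seed.  It
    is deterministic per seed and untrained — it carries coarse spatial
    color structure, not learned semantics.
    """

    def __init__(self, width: int = 4096, seed: int = 0, grid: int = 16):
        self.width = int(width)
        self.seed = int(seed)
        self.grid = int(grid)
        rng = np.random.default_rng(seed)
        self._w = rng.standard_normal((self.width, grid * grid * 3)) / np.sqrt(
            grid * grid * 3
        )

    def __call__(self, image: np.ndarray) -> np.ndarray:
        arr = np.asarray(image, dtype=np.float64)
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        h, w = arr.shape[:2]
        g = self.grid
        rows = np.linspace(0, h, g + 1).astype(int)
        cols = np.linspace(0, w, g + 1).astype(int)
        pooled = np.empty((g, g, 3))
        for a in range(g):
            for b in range(g):
                pooled[a, b] = arr[rows[a] : rows[a + 1], cols[b] : cols[b + 1]].mean(
                    axis=(0, 1)
                )
        return self._w @ (pooled.reshape(-1) / 255.0)


def deep_extract(image: np.ndarray, extractor=None) -> FeatureVector:
    """Run a pluggable embedding extractor and tag its output as 'deep'.

    The extractor must expose a ``width`` attribute and return exactly that
    many values; a mismatch is a contract violation.
    """
    if extractor is None:
        extractor = RandomProjectionExtractor()
    vec = np.asarray(extractor(image), dtype=np.float64).ravel()
    if vec.size != extractor.width:
        raise ContractError(
            f"extractor declared width {extractor.width} but returned {vec.size}"
        )
    return FeatureVector(values=vec, block_labels=["deep"] * vec.size)


def fuse_deep(deep: FeatureVector, handcrafted: FeatureVector) -> FeatureVector:
    """Concatenate deep-then-handcrafted into the hybrid vector.

    The handcrafted block must be the full lbp+glcm+fch fusion.
    """
    required = {"lbp", "glcm", "fch"}
    present = set(handcrafted.block_labels)
    if not required <= present:
        missing = sorted(required - present)
        raise ContractError(f"handcrafted vector missing blocks: {missing}")
    return fuse([deep, handcrafted])
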