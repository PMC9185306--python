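"""Region-based active-contour (level-set) lesion segmentation.

The model is a signed-pressure-force (SPF) level set in the Chan–Vese
family.  A signed field φ is initialized as a disc around a user seed;
inside/outside region means c1 and c2 are computed with a smoothed Heaviside
weight; the SPF term

    spf(I) = (I − (c1 + c2)/2) / max|I − (c1 + c2)/2|

drives φ outward where the pixel looks like the seeded region and inward
elsewhere:

    φ ← φ + dt · spf(I) · (λ·|∇φ| + ν)

followed by a small Gaussian smoothing of φ that stands in for the usual
curvature regularization.  Evolution stops when the relative change of the
positive-φ area between successive iterations falls below a stop value SV
(percent), or after ``max_iter`` iterations.  The final mask is
hole-filled and restricted to the connected component containing the seed,
so a single lesion is isolated from the rest of the frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import DegenerateRegionError, ImageFormatError, ParameterError

__all__ = [
    "ContourParams",
    "LevelSetState",
    "initialize_level_set",
    "region_means",
    "evolve_step",
    "stop_criterion",
    "segment",
    "fill_holes",
    "smoothed_heaviside",
]


@dataclass
class ContourParams:
    """Tunables of the level-set evolution.

    lam
        weight λ > 0 on the |∇φ| (length/propagation) term.
    nu
        signed balloon weight ν; positive inflates, negative deflates.
    eps
        width ε (pixels) of the smoothed Heaviside used for region means.
    dt
        time step of the explicit update.
    sv
        stop value in percent: stop when |ΔA| < (sv/100)·A_old.
    max_iter
        hard iteration cap; evolution never runs past it.
    seed
        (row, col) initial point.
    radius
        radius of the initial disc around the seed, ≥ 2 pixels.
    smooth_sigma
        σ of the per-step Gaussian regularization of φ.
    """

    seed: tuple[int, int]
    radius: float = 5.0
    lam: float = 1.0
    nu: float = 0.0
    eps: float = 1.5
    dt: float = 1.0
    sv: float = 0.1
    max_iter: int = 500
    smooth_sigma: float = 0.7

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ParameterError(f"lam must be > 0, got {self.lam}")
        if self.eps <= 0 or self.dt <= 0 or self.sv <= 0:
            raise ParameterError("eps, dt and sv must all be > 0")
        if self.max_iter < 1:
            raise ParameterError("max_iter must be ≥ 1")
        if self.radius < 2:
            raise ParameterError(f"initial radius must be ≥ 2, got {self.radius}")


@dataclass
class LevelSetState:
    """φ field plus bookkeeping; ``mask`` is always indicator(φ > 0)."""

    phi: np.ndarray
    mask: np.ndarray
    c1: float | None = None
    c2: float | None = None
    iteration: int = 0
    converged: bool = False
    stop_reason: str = ""
    area_history: list = field(default_factory=list)

    def area(self) -> int:
        return int(self.mask.sum())


def smoothed_heaviside(t: np.ndarray, eps: float) -> np.ndarray:
    """Hε(t) = ½·(1 + (2/π)·arctan(t/ε))."""
    return 0.5 * (1.0 + (2.0 / np.pi) * np.arctan(np.asarray(t, float) / eps))


def initialize_level_set(
    shape: tuple[int, int], seed: tuple[int, int], radius: float = 5.0
) -> LevelSetState:
    """Signed distance to a seeded disc: φ = radius − distance-to-seed."""
    h, w = shape
    r, c = seed
    if not (0 <= r < h and 0 <= c < w):
        raise ParameterError(f"seed {seed} outside image bounds {shape}")
    if radius < 2:
        raise ParameterError(f"initial radius must be ≥ 2, got {radius}")
    rows, cols = np.mgrid[0:h, 0:w]
    dist = np.hypot(rows - r, cols - c)
    # tiny offset so pixel centers exactly on the circle count as inside,
    # which keeps the discrete disc area near π·r²
    phi = radius + 1e-6 - dist
    return LevelSetState(phi=phi, mask=phi > 0, area_history=[int((phi > 0).sum())])


def region_means(
    gray: np.ndarray,
    state: LevelSetState,
    eps: float = 1.5,
    domain: np.ndarray | None = None,
) -> tuple[float, float]:
    """Smoothed-Heaviside-weighted inside/outside intensity means.

    c1 = Σ I·Hε(φ)·M / Σ Hε(φ)·M and c2 = Σ I·(1−Hε(φ))·M / Σ (1−Hε(φ))·M,
    where M is an optional characteristic function restricting the domain
    of interest (the whole frame when omitted).
    """
    img = np.asarray(gray, dtype=np.float64)
    if img.shape != state.phi.shape:
        raise ImageFormatError("image and φ shapes differ")
    m = np.ones_like(img) if domain is None else np.asarray(domain, float)
    if not ((state.phi > 0) & (m > 0)).any():
        raise DegenerateRegionError("inside region is empty")
    if not ((state.phi <= 0) & (m > 0)).any():
        raise DegenerateRegionError("outside region is empty")
    h_in = smoothed_heaviside(state.phi, eps) * m
    h_out = (1.0 - smoothed_heaviside(state.phi, eps)) * m
    denom_in = h_in.sum()
    denom_out = h_out.sum()
    c1 = float((img * h_in).sum() / denom_in)
    c2 = float((img * h_out).sum() / denom_out)
    return c1, c2


def evolve_step(
    gray: np.ndarray, state: LevelSetState, params: ContourParams
) -> LevelSetState:
    """One explicit SPF update of φ, followed by Gaussian re-regularization.

    A flat (all-constant) image leaves the SPF undefined; the state is
    returned unchanged with ``converged`` set.
    """
    img = np.asarray(gray, dtype=np.float64)
    if img.max() == img.min():
        return replace(state, converged=True, stop_reason="flat image")
    if not state.mask.any():
        return replace(state, converged=True, stop_reason="contour vanished")
    if state.mask.all():
        return replace(state, converged=True, stop_reason="contour filled the frame")
    c1, c2 = region_means(img, state, eps=params.eps)
    drive = img - 0.5 * (c1 + c2)
    peak = np.abs(drive).max()
    if peak == 0.0:
        return replace(state, c1=c1, c2=c2, converged=True, stop_reason="flat image")
    spf = drive / peak
    gy, gx = np.gradient(state.phi)
    grad_mag = np.hypot(gy, gx)
    phi = state.phi + params.dt * spf * (params.lam * grad_mag + params.nu)
    if params.smooth_sigma > 0:
        phi = ndimage.gaussian_filter(phi, params.smooth_sigma)
    mask = phi > 0
    history = state.area_history + [int(mask.sum())]
    return LevelSetState(
        phi=phi,
        mask=mask,
        c1=c1,
        c2=c2,
        iteration=state.iteration + 1,
        area_history=history,
    )


def stop_criterion(area_old: int, area_new: int, sv: float) -> bool:
    """Relative-area-change stop rule: |A_new − A_old| < (sv/100)·A_old."""
    if area_old < 0 or area_new < 0:
        raise ParameterError("areas must be non-negative")
    if sv <= 0:
        raise ParameterError(f"sv must be > 0, got {sv}")
    if area_old == 0:
        return True
    return abs(area_new - area_old) < (sv / 100.0) * area_old


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background regions not 4-connected to the image border."""
    m = np.asarray(mask).astype(bool)
    structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    return ndimage.binary_fill_holes(m, structure=structure)


def _seed_component(mask: np.ndarray, seed: tuple[int, int]) -> np.ndarray:
    """Connected component (8-connectivity) of ``mask`` containing the seed."""
    labels, _ = ndimage.label(mask, structure=np.ones((3, 3)))
    lab = labels[seed]
    if lab == 0:
        # Seed fell outside the final mask; keep the component nearest to it.
        if not mask.any():
            return mask
        fg = np.argwhere(mask)
        nearest = fg[np.argmin(((fg - np.array(seed)) ** 2).sum(axis=1))]
        lab = labels[tuple(nearest)]
    return labels == lab


def segment(gray: np.ndarray, params: ContourParams) -> tuple[np.ndarray, LevelSetState]:
    """Run the level set to convergence and isolate the seeded lesion.

    Returns ``(mask, final_state)``; the mask is hole-filled and restricted
    to the connected component containing the seed.  ``final_state.stop_reason``
    records which stop condition fired.
    """
    img = np.asarray(gray, dtype=np.float64)
    state = initialize_level_set(img.shape, params.seed, params.radius)
    while state.iteration < params.max_iter:
        area_old = state.area()
        state = evolve_step(img, state, params)
        if state.converged:
            break
        if stop_criterion(area_old, state.area(), params.sv):
            state.converged = True
            state.stop_reason = f"area change below SV={params.sv}%"
            break
    if not state.stop_reason:
        state.stop_reason = (
            "flat image" if state.converged else f"max_iter={params.max_iter} reached"
        )
    mask = fill_holes(state.mask)
    mask = _seed_component(mask, params.seed)
    return mask, state
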