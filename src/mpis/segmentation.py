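"""Classical tumor-region segmentation on slide images.

The stage mirrors the standard whole-slide pipeline: an Otsu threshold on the
gray histogram separates stained tissue from the white slide background; a
224x224 non-overlapping window is slid over the tissue region and each patch
scored by a pluggable classifier returning a tumor probability; the resulting
heatmap is binarized by Otsu again and the largest connected component kept
as the tumor mask.

The patch classifier is deliberately an interface: any callable mapping a
patch to a probability in [0, 1] plugs in. The default scorer is a logistic
function of mean patch darkness relative to a background reference, which is
sufficient for intensity-separable tumors and keeps the pipeline end-to-end
testable without a trained network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage

from .features import to_grayscale

__all__ = [
    "otsu_threshold",
    "tissue_mask",
    "default_scorer",
    "constant_scorer",
    "classify_patches",
    "heatmap_to_tumor_mask",
    "segment_slide",
    "WINDOW",
]

WINDOW = 224  # sliding-window side, pixels at base magnification


def otsu_threshold(histogram: np.ndarray) -> tuple[int, bool]:
    """Threshold maximizing between-class variance over a 256-bin histogram.

    Classes are ``gray <= t`` and ``gray > t``. Ties are broken by the
    smallest qualifying threshold. Returns ``(threshold, degenerate)`` where
    the degenerate flag marks single-valued histograms (the threshold is then
    that single value and no split exists).
    """
    h = np.asarray(histogram, dtype=float)
    if h.ndim != 1 or len(h) != 256:
        raise ValueError("histogram must have 256 bins")
    if h.sum() <= 0:
        raise ValueError("histogram is empty")
    nonzero = np.nonzero(h)[0]
    if len(nonzero) == 1:
        return int(nonzero[0]), True

    p = h / h.sum()
    bins = np.arange(256)
    omega = np.cumsum(p)                     # P(gray <= t)
    mu = np.cumsum(p * bins)                 # partial mean
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b = np.nan_to_num(sigma_b, nan=-1.0, posinf=-1.0, neginf=-1.0)
    return int(np.argmax(sigma_b)), False


def tissue_mask(image: np.ndarray, fill_holes: bool = True) -> np.ndarray:
    """Binary tissue mask: pixels darker than the Otsu threshold of the slide.

    White (255) background is excluded by construction; holes in the tissue
    are filled morphologically. A degenerate (single-valued) histogram yields
    an all-tissue mask unless the constant is white.
    """
    gray = to_grayscale(np.asarray(image))
    if gray.size == 0:
        raise ValueError("empty image")
    hist = np.bincount(gray.ravel(), minlength=256)
    t, degenerate = otsu_threshold(hist)
    if degenerate:
        mask = gray < 255 if t == 255 else np.ones_like(gray, dtype=bool)
    else:
        mask = gray <= t
    if fill_holes and mask.any():
        mask = ndimage.binary_fill_holes(mask)
    return mask


def default_scorer(background_reference: float = 255.0,
                   steepness: float = 0.1) -> Callable[[np.ndarray], float]:
    """Logistic scorer of patch darkness: darker patches score closer to 1.

    ``p = sigmoid(steepness * (background_reference - mean(patch) - 1/(2*steepness)))``
    centered so a patch at half the reference contrast scores 0.5.
    """
    center = background_reference - 0.5 / steepness

    def score(patch: np.ndarray) -> float:
        m = float(to_grayscale(patch).mean())
        return float(1.0 / (1.0 + np.exp(-steepness * (center - m))))

    return score


def constant_scorer(p: float) -> Callable[[np.ndarray], float]:
    """Scorer returning a fixed probability (diagnostic plumbing)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("probability must be in [0, 1]")
    return lambda patch: p


def classify_patches(slide: np.ndarray, tissue: np.ndarray,
                     scorer: Callable[[np.ndarray], float],
                     window: int = WINDOW) -> np.ndarray:
    """Score non-overlapping windows over the tissue region.

    Heatmap cell (r, c) covers rows [window*r, window*(r+1)) and the matching
    columns (0-based, half-open). Edge windows that do not fully fit are
    discarded; windows with no tissue pixel are skipped with probability 0.
    """
    gray = to_grayscale(np.asarray(slide))
    if tissue.shape != gray.shape:
        raise ValueError("tissue mask shape does not match slide")
    n_rows = gray.shape[0] // window
    n_cols = gray.shape[1] // window
    heat = np.zeros((n_rows, n_cols))
    for r in range(n_rows):
        for c in range(n_cols):
            sl = (slice(window * r, window * (r + 1)),
                  slice(window * c, window * (c + 1)))
            if not tissue[sl].any():
                continue
            p = float(scorer(gray[sl]))
            if not 0.0 <= p <= 1.0:
                raise ValueError(
                    f"scorer returned {p} outside [0, 1] at cell ({r}, {c})")
            heat[r, c] = p
    return heat


def _largest_component(binary: np.ndarray, connectivity: int = 8) -> np.ndarray:
    structure = np.ones((3, 3)) if connectivity == 8 else None
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return np.zeros_like(binary, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    best = int(np.max(sizes))
    candidates = [k + 1 for k, s in enumerate(sizes) if int(s) == best]
    if len(candidates) == 1:
        return labels == candidates[0]
    # tie: keep the component whose top-left-most cell comes first row-major
    def origin(k):
        rr, cc = np.nonzero(labels == k)
        order = np.lexsort((cc, rr))
        return (rr[order[0]], cc[order[0]])
    keep = min(candidates, key=origin)
    return labels == keep


def heatmap_to_tumor_mask(heatmap: np.ndarray,
                          connectivity: int = 8) -> np.ndarray:
    """Binarize a probability heatmap by Otsu and keep the largest component.

    Probabilities are quantized to 256 bins of [0, 1] for the Otsu histogram.
    Component extraction uses 8-connectivity by default (4 available); ties in
    size are broken by the smallest top-left origin. An all-zero heatmap
    yields an empty mask with a warning.
    """
    heat = np.asarray(heatmap, dtype=float)
    if heat.size == 0:
        raise ValueError("empty heatmap")
    if heat.max() == 0:
        warnings.warn("all-zero heatmap: empty tumor mask")
        return np.zeros_like(heat, dtype=bool)
    bins = np.clip((heat * 255).round().astype(int), 0, 255)
    t, degenerate = otsu_threshold(np.bincount(bins.ravel(), minlength=256))
    binary = bins > t if not degenerate else bins >= t
    return _largest_component(binary, connectivity=connectivity)


@dataclass
class SegmentationResult:
    """Artifacts of the segmentation stage for one slide."""

    tissue: np.ndarray       # bool, slide resolution
    heatmap: np.ndarray      # float, one cell per window
    tumor_cells: np.ndarray  # bool, heatmap resolution

    def tumor_mask_at(self, downsample: int, window: int = WINDOW) -> np.ndarray:
        """Upsample the cell-level tumor mask to 1/downsample of base pixels."""
        if window % downsample:
            raise ValueError("window must be divisible by the downsample factor")
        k = window // downsample
        return np.kron(self.tumor_cells, np.ones((k, k), dtype=bool))


def segment_slide(slide: np.ndarray,
                  scorer: Callable[[np.ndarray], float] | None = None,
                  window: int = WINDOW,
                  connectivity: int = 8) -> SegmentationResult:
    """Full segmentation stage: tissue mask -> patch scores -> tumor mask."""
    if scorer is None:
        scorer = default_scorer()
    tissue = tissue_mask(slide)
    heat = classify_patches(slide, tissue, scorer, window=window)
    if heat.size == 0:
        tumor = np.zeros_like(heat, dtype=bool)
    else:
        tumor = heatmap_to_tumor_mask(heat, connectivity=connectivity)
    return SegmentationResult(tissue=tissue, heatmap=heat, tumor_cells=tumor)
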