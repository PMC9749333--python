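"""Texture feature engine: quantization, first-order, GLCM and GLRLM features.

Each analysis scale (2.5x, 10x, 40x) contributes 68 features -- 17 first-order
statistics, 7 gray-level co-occurrence matrix (GLCM) features at angle 0, and
11 run-length (GLRLM) features at each of four angles -- for a catalog of 204
descriptors per slide. All computations accept a validity mask so that
features of irregular regions (e.g. the 2.5x whole-tumor crop) are computed
only over in-region pixels.

Conventions
-----------
* Gray levels are quantized to ``1..n_gray`` with equal-width bins over the
  fixed 8-bit range [0, 255]; the fixed range keeps low/high-gray-level
  emphasis features comparable across tiles.
* GLCM: distance 1, angle 0 (horizontal), symmetrized and normalized.
* GLRLM angles map to (row, col) offsets 0->(0,+1), 45->(-1,+1), 90->(-1,0),
  135->(-1,-1); runs are maximal same-level segments along that direction,
  broken by mask boundaries.
* Kurtosis is Pearson (non-excess; a normal distribution scores 3); the
  zero-variance guard returns 0 for both skewness and kurtosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FeatureDescriptor",
    "FeatureVector",
    "QuantizedTile",
    "quantize",
    "first_order_features",
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_features",
    "feature_catalog",
    "tile_features",
    "slide_feature_vector",
    "SCALES",
    "FIRST_ORDER_NAMES",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "GLRLM_ANGLES",
]

# Luminance weights for RGB -> gray conversion (ITU-R BT.601).
_LUMA = np.array([0.299, 0.587, 0.114])

SCALES = (2.5, 10, 40)

FIRST_ORDER_NAMES = (
    "Mean", "Median", "Minimum", "Maximum", "Range", "Variance", "StdDev",
    "Skewness", "Kurtosis", "Energy", "Entropy", "Uniformity", "MAD", "RMS",
    "Percentile_10th", "Percentile_90th", "IQR",
)

GLCM_NAMES = (
    "ASM", "contrast", "correlation", "dissimilarity", "homogeneity",
    "entropy", "max_probability",
)

GLRLM_NAMES = (
    "SRE", "LRE", "GLN", "RLN", "RP",
    "LGLRE", "HGLRE", "SRLGLE", "SRHGLE", "LRLGLE", "LRHGLE",
)

GLRLM_ANGLES = (0, 45, 90, 135)

# angle (degrees) -> (row, col) step
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def _scale_token(scale: float) -> str:
    return f"{scale:g}"


@dataclass(frozen=True)
class FeatureDescriptor:
    """Canonical identity of one catalog feature.

    The canonical id strings follow the field's naming for texture
    signatures: first-order features are ``<Name>_<scale>`` (e.g.
    ``Kurtosis_10``), GLCM features ``glcm_<name>_<angle>_<scale>`` and
    run-length features ``glrlm_<NAME>_<angle>_<scale>`` (e.g.
    ``glrlm_SRLGLE_90_2.5``).
    """

    family: str          # 'firstorder' | 'glcm' | 'glrlm'
    name: str
    angle: int | None    # None for firstorder, 0 for glcm, 0/45/90/135 for glrlm
    scale: float         # 2.5 | 10 | 40

    @property
    def canonical_id(self) -> str:
        tok = _scale_token(self.scale)
        if self.family == "firstorder":
            return f"{self.name}_{tok}"
        return f"{self.family}_{self.name}_{self.angle}_{tok}"

    @classmethod
    def parse(cls, canonical_id: str) -> "FeatureDescriptor":
        """Inverse of :attr:`canonical_id`."""
        parts = canonical_id.split("_")
        if parts[0] in ("glcm", "glrlm"):
            family = parts[0]
            scale = float(parts[-1])
            angle = int(parts[-2])
            name = "_".join(parts[1:-2])
        else:
            family = "firstorder"
            scale = float(parts[-1])
            angle = None
            name = "_".join(parts[:-1])
        desc = cls(family, name, angle, scale)
        if desc.canonical_id != canonical_id:
            raise ValueError(f"unparseable feature id: {canonical_id!r}")
        return desc


def feature_catalog(scales: tuple[float, ...] = SCALES) -> list[FeatureDescriptor]:
    """The canonical descriptor list: 68 per scale, 204 for the default three.

    Per scale: 17 first-order + 7 GLCM (angle 0) + 11 GLRLM x 4 angles.
    """
    catalog: list[FeatureDescriptor] = []
    for scale in scales:
        for name in FIRST_ORDER_NAMES:
            catalog.append(FeatureDescriptor("firstorder", name, None, scale))
        for name in GLCM_NAMES:
            catalog.append(FeatureDescriptor("glcm", name, 0, scale))
        for angle in GLRLM_ANGLES:
            for name in GLRLM_NAMES:
                catalog.append(FeatureDescriptor("glrlm", name, angle, scale))
    ids = [d.canonical_id for d in catalog]
    assert len(set(ids)) == len(ids)
    return catalog


@dataclass
class QuantizedTile:
    """Integer gray levels in ``1..n_gray`` plus a pixel validity mask."""

    levels: np.ndarray   # int array, shape (H, W)
    valid: np.ndarray    # bool array, shape (H, W)
    n_gray: int

    def __post_init__(self):
        inside = self.levels[self.valid]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_gray):
            raise ValueError("quantized levels outside [1, n_gray]")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) image to 8-bit gray by luminance; pass gray through."""
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] in (3, 4):
        gray = image[..., :3].astype(float) @ _LUMA
        return np.clip(np.round(gray), 0, 255).astype(np.uint8)
    raise ValueError(f"expected 2-D gray or 3-D RGB image, got shape {image.shape}")


def quantize(tile: np.ndarray, valid: np.ndarray | None = None,
             n_gray: int = 16) -> QuantizedTile:
    """Equal-width quantization of an 8-bit tile into ``1..n_gray`` levels.

    ``level = floor(value * n_gray / 256) + 1`` over the fixed range [0, 255];
    value 0 maps to level 1 and value 255 to level ``n_gray``.
    """
    if n_gray < 2:
        raise ValueError("n_gray must be >= 2")
    gray = to_grayscale(np.asarray(tile))
    if valid is None:
        valid = np.ones(gray.shape, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    if valid.shape != gray.shape:
        raise ValueError("validity mask shape does not match tile")
    levels = (gray.astype(np.int64) * n_gray) // 256 + 1
    return QuantizedTile(levels=levels, valid=valid, n_gray=n_gray)


# ---------------------------------------------------------------------------
# First-order statistics
# ---------------------------------------------------------------------------

def first_order_features(tile: np.ndarray, valid: np.ndarray | None = None,
                         n_gray: int = 16) -> dict[str, float]:
    """The 17 first-order intensity statistics over valid pixels.

    Entropy and Uniformity are computed over the ``n_gray``-bin histogram of
    the quantized intensities (entropy in bits); Variance is the population
    variance; percentiles use linear interpolation between order statistics.
    """
    gray = to_grayscale(np.asarray(tile))
    if valid is None:
        valid = np.ones(gray.shape, dtype=bool)
    x = gray[np.asarray(valid, dtype=bool)].astype(float)
    if x.size == 0:
        raise ValueError("first_order_features requires >= 1 valid pixel")

    mean = float(x.mean())
    var = float(x.var())          # population variance
    sd = float(np.sqrt(var))
    if sd > 0:
        z = (x - mean) / sd
        skew = float(np.mean(z ** 3))
        kurt = float(np.mean(z ** 4))   # Pearson: normal -> 3
    else:
        skew = 0.0
        kurt = 0.0

    q = quantize(gray, valid, n_gray=n_gray)
    counts = np.bincount(q.levels[q.valid].ravel(), minlength=n_gray + 1)[1:]
    p = counts / counts.sum()
    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    uniformity = float((p ** 2).sum())

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    return {
        "Mean": mean,
        "Median": float(p50),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(x.max() - x.min()),
        "Variance": var,
        "StdDev": sd,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": float((x ** 2).sum()),
        "Entropy": entropy,
        "Uniformity": uniformity,
        "MAD": float(np.abs(x - mean).mean()),
        "RMS": float(np.sqrt((x ** 2).mean())),
        "Percentile_10th": float(p10),
        "Percentile_90th": float(p90),
        "IQR": float(p75 - p25),
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def glcm_matrix(q: QuantizedTile) -> np.ndarray:
    """Symmetrized, normalized co-occurrence matrix at distance 1, angle 0.

    Ordered horizontal pairs with both pixels valid are counted, the
    transpose added, and the matrix normalized to sum 1. Returns an all-zero
    matrix when no valid pair exists.
    """
    lv, vd, ng = q.levels, q.valid, q.n_gray
    pair_ok = vd[:, :-1] & vd[:, 1:]
    a = lv[:, :-1][pair_ok] - 1
    b = lv[:, 1:][pair_ok] - 1
    counts = np.zeros((ng, ng))
    np.add.at(counts, (a, b), 1.0)
    counts = counts + counts.T
    total = counts.sum()
    if total > 0:
        counts /= total
    return counts


def glcm_features(q: QuantizedTile) -> dict[str, float]:
    """The 7 Haralick-style GLCM features at angle 0, distance 1.

    Returns NaN for every feature when the tile has no valid horizontal
    pair. The correlation guard returns 0 when a marginal is degenerate.
    """
    P = glcm_matrix(q)
    if P.sum() == 0:
        return {name: float("nan") for name in GLCM_NAMES}
    ng = q.n_gray
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, ng + 1)[None, :]
    pi = P.sum(axis=1)
    mu_i = float((np.arange(1, ng + 1) * pi).sum())
    sigma_i = float(np.sqrt(((np.arange(1, ng + 1) - mu_i) ** 2 * pi).sum()))
    # symmetric matrix: both marginals coincide
    if sigma_i > 0:
        correlation = float(((i - mu_i) * (j - mu_i) * P).sum() / sigma_i ** 2)
    else:
        correlation = 0.0
    nz = P[P > 0]
    return {
        "ASM": float((P ** 2).sum()),
        "contrast": float(((i - j) ** 2 * P).sum()),
        "correlation": correlation,
        "dissimilarity": float((np.abs(i - j) * P).sum()),
        "homogeneity": float((P / (1.0 + (i - j) ** 2)).sum()),
        "entropy": float(-(nz * np.log2(nz)).sum()),
        "max_probability": float(P.max()),
    }


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def _angle_sequence(q: QuantizedTile, angle: int) -> np.ndarray:
    """Flatten the tile into one 1-D sequence of lines along the angle.

    Valid pixels carry their level (1..n_gray); invalid pixels and the
    padding separating lines are 0, so a vectorized run-length encoding of
    the sequence never merges runs across lines or mask boundaries.
    """
    arr = np.where(q.valid, q.levels, 0).astype(np.int64)
    h, w = arr.shape
    if angle == 90:
        arr = arr.T
        h, w = w, h
        angle = 0
    if angle == 0:
        padded = np.zeros((h, w + 1), dtype=np.int64)
        padded[:, :w] = arr
        return padded.ravel()
    if angle == 135:
        arr = np.fliplr(arr)
        angle = 45
    if angle != 45:
        raise ValueError(f"angle must be one of {GLRLM_ANGLES}")
    # skew rows so anti-diagonals (direction (-1,+1)) become columns:
    # skew[r, r + c] = arr[r, c], i.e. column r+c collects one anti-diagonal
    skew = np.zeros((h + 1, w + h), dtype=np.int64)
    for r in range(h):
        skew[r, r:r + w] = arr[r]
    return skew.ravel(order="F")


def glrlm_matrix(q: QuantizedTile, angle: int) -> np.ndarray:
    """Run-length counts p(i, j): level i (rows, 1..n_gray) by length j.

    Runs are maximal same-level segments along the angle's line direction;
    invalid pixels break runs and are never counted, so pixel conservation
    ``sum_ij j * p(i,j) == n_valid`` holds at every angle.
    """
    seq = _angle_sequence(q, angle)
    max_run = max(q.levels.shape)
    p = np.zeros((q.n_gray, max_run))
    change = np.flatnonzero(seq[1:] != seq[:-1])
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change + 1, [len(seq)]))
    vals = seq[starts]
    keep = vals > 0
    np.add.at(p, (vals[keep] - 1, (ends - starts)[keep] - 1), 1.0)
    # trim trailing all-zero length columns (keeps matrices small)
    if p.any():
        last = np.nonzero(p.sum(axis=0))[0][-1]
        p = p[:, : last + 1]
    return p


def glrlm_features(q: QuantizedTile, angle: int) -> dict[str, float]:
    """The 11 classic run-length features at one angle.

    Short/long-run and low/high-gray-level emphases weight run counts by
    inverse or direct squared run length j and gray level i.
    """
    p = glrlm_matrix(q, angle)
    n_r = p.sum()
    n_p = int(q.valid.sum())
    if n_r == 0:
        return {name: float("nan") for name in GLRLM_NAMES}
    i = np.arange(1, p.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, p.shape[1] + 1, dtype=float)[None, :]
    pi = p.sum(axis=1)   # per-level totals
    pj = p.sum(axis=0)   # per-length totals
    return {
        "SRE": float((p / j ** 2).sum() / n_r),
        "LRE": float((p * j ** 2).sum() / n_r),
        "GLN": float((pi ** 2).sum() / n_r),
        "RLN": float((pj ** 2).sum() / n_r),
        "RP": float(n_r / n_p),
        "LGLRE": float((p / i ** 2).sum() / n_r),
        "HGLRE": float((p * i ** 2).sum() / n_r),
        "SRLGLE": float((p / (i ** 2 * j ** 2)).sum() / n_r),
        "SRHGLE": float((p * i ** 2 / j ** 2).sum() / n_r),
        "LRLGLE": float((p * j ** 2 / i ** 2).sum() / n_r),
        "LRHGLE": float((p * i ** 2 * j ** 2).sum() / n_r),
    }


# ---------------------------------------------------------------------------
# Per-tile and per-slide assembly
# ---------------------------------------------------------------------------

def tile_features(tile: np.ndarray, valid: np.ndarray | None = None,
                  scale: float = 40, n_gray: int = 16) -> dict[str, float]:
    """All 68 features of one tile at one scale, keyed by canonical id."""
    q = quantize(tile, valid, n_gray=n_gray)
    tok = _scale_token(scale)
    out: dict[str, float] = {}
    for name, v in first_order_features(tile, valid, n_gray=n_gray).items():
        out[f"{name}_{tok}"] = v
    for name, v in glcm_features(q).items():
        out[f"glcm_{name}_0_{tok}"] = v
    for angle in GLRLM_ANGLES:
        for name, v in glrlm_features(q, angle).items():
            out[f"glrlm_{name}_{angle}_{tok}"] = v
    return out


@dataclass
class FeatureVector:
    """Per-slide feature values keyed by canonical id, with a completeness flag."""

    slide_id: str
    values: dict[str, float] = field(default_factory=dict)

    @property
    def complete(self) -> bool:
        ids = {d.canonical_id for d in feature_catalog()}
        return ids <= set(self.values) and all(
            np.isfinite(self.values[i]) for i in ids
        )

    def missing_ids(self) -> list[str]:
        have = {k for k, v in self.values.items() if np.isfinite(v)}
        return [d.canonical_id for d in feature_catalog() if d.canonical_id not in have]

    def to_series(self) -> pd.Series:
        ids = [d.canonical_id for d in feature_catalog()]
        return pd.Series({i: self.values.get(i, np.nan) for i in ids},
                         name=self.slide_id)


def slide_feature_vector(slide_id: str,
                         tiles_by_scale: dict[float, list[tuple[np.ndarray, np.ndarray | None]]],
                         n_gray: int = 16,
                         aggregation: str = "mean") -> FeatureVector:
    """Aggregate per-tile features to one vector per slide.

    ``tiles_by_scale`` maps scale token -> list of (image, validity-mask)
    pairs; the 2.5x entry carries the single whole-region crop, the 10x/40x
    entries one pair per tile. Aggregation across tiles within a scale is the
    unweighted mean by default ('median' is available); a scale with no tiles
    yields an incomplete vector with its ids missing.
    """
    if aggregation not in ("mean", "median"):
        raise ValueError("aggregation must be 'mean' or 'median'")
    agg = np.nanmean if aggregation == "mean" else np.nanmedian
    values: dict[str, float] = {}
    for scale, tiles in tiles_by_scale.items():
        if not tiles:
            continue
        per_tile = [tile_features(img, valid, scale=scale, n_gray=n_gray)
                    for img, valid in tiles]
        for key in per_tile[0]:
            values[key] = float(agg([t[key] for t in per_tile]))
    return FeatureVector(slide_id=slide_id, values=values)
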