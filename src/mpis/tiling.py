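"""Multi-scale tile acquisition from the tumor region.

From a base-resolution slide (nominal 40x) the pyramid exposes three
analysis levels with fixed downsample factors {40x: 1, 10x: 4, 2.5x: 16}.
The 2.5x whole-tumor crop is taken directly under the irregular region mask;
at 10x and 40x a non-overlapping 1024x1024 grid is laid over the tumor-mask
bounding box, tiles with strictly more than 75% of their pixels inside the
tumor mask are kept, and at 40x a seeded uniform sample caps the tile count
at 200 per slide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SlidePyramid",
    "Tile",
    "extract_region_2p5x",
    "enumerate_tiles",
    "sample_tiles",
    "reinhard_stats",
    "color_normalize",
    "DOWNSAMPLE",
    "TILE_SIZE",
    "SAMPLE_CAP",
]

DOWNSAMPLE = {40: 1, 10: 4, 2.5: 16}
TILE_SIZE = 1024
SAMPLE_CAP = 200


def _downscale(image: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downscale by an integer factor (trailing remainder cropped)."""
    if factor == 1:
        return image
    h, w = image.shape[:2]
    h2, w2 = h // factor, w // factor
    img = image[: h2 * factor, : w2 * factor].astype(float)
    if img.ndim == 2:
        blocks = img.reshape(h2, factor, w2, factor)
        out = blocks.mean(axis=(1, 3))
    else:
        blocks = img.reshape(h2, factor, w2, factor, img.shape[2])
        out = blocks.mean(axis=(1, 3))
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


@dataclass
class SlidePyramid:
    """Base-resolution slide with derived lower-magnification levels."""

    base: np.ndarray
    downsample: dict[float, int] = field(default_factory=lambda: dict(DOWNSAMPLE))
    _cache: dict[float, np.ndarray] = field(default_factory=dict, repr=False)

    def level(self, scale: float) -> np.ndarray:
        if scale not in self.downsample:
            raise ValueError(f"unknown scale {scale}; have {sorted(self.downsample)}")
        if scale not in self._cache:
            self._cache[scale] = _downscale(self.base, self.downsample[scale])
        return self._cache[scale]

    def region(self, scale: float, row0: int, col0: int,
               height: int, width: int) -> np.ndarray:
        """Crop (row0, col0, height, width) at a level; out-of-bounds is an error."""
        img = self.level(scale)
        if row0 < 0 or col0 < 0 or row0 + height > img.shape[0] \
                or col0 + width > img.shape[1]:
            raise ValueError(
                f"requested box ({row0},{col0})+({height}x{width}) exceeds "
                f"level bounds {img.shape[:2]} at scale {scale}")
        return img[row0:row0 + height, col0:col0 + width]


@dataclass
class Tile:
    """One analysis image with its provenance and tissue coverage."""

    image: np.ndarray
    scale: float
    origin: tuple[int, int]          # (row, col) at the tile's level
    tissue_fraction: float
    mask: np.ndarray | None = None   # in-region pixel mask (2.5x crops)


def _mask_at_level(tumor_cells: np.ndarray, window: int, downsample: int) -> np.ndarray:
    """Upsample a heatmap-cell tumor mask to a pyramid level's pixel grid."""
    if window % downsample:
        raise ValueError("window size must be divisible by the downsample factor")
    k = window // downsample
    return np.kron(tumor_cells, np.ones((k, k), dtype=bool))


def extract_region_2p5x(pyramid: SlidePyramid, tumor_cells: np.ndarray,
                        window: int = 224, scale: float = 2.5) -> Tile:
    """Whole-tumor crop at 2.5x with the irregular in-region pixel mask.

    The crop is the tumor-mask bounding box at the 2.5x level; pixels outside
    the (possibly non-rectangular) region are flagged excluded in the tile's
    mask rather than recolored, so downstream features see only in-region
    pixels.
    """
    if not tumor_cells.any():
        raise ValueError("no tumor region")
    mask = _mask_at_level(tumor_cells, window, pyramid.downsample[scale])
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    img = pyramid.region(scale, r0, c0, r1 - r0, c1 - c0)
    sub = mask[r0:r1, c0:c1]
    return Tile(image=img, scale=scale, origin=(r0, c0),
                tissue_fraction=float(sub.mean()), mask=sub)


def enumerate_tiles(pyramid: SlidePyramid, tumor_cells: np.ndarray,
                    scale: float, tissue_fraction_min: float = 0.75,
                    tile_size: int = TILE_SIZE, window: int = 224) -> list[Tile]:
    """Non-overlapping tile grid over the tumor-region bounding box.

    The grid is anchored at the bounding-box origin; only full tiles fitting
    inside the box are considered; a tile is kept iff its in-tumor-mask pixel
    fraction is strictly greater than ``tissue_fraction_min``. Tiles are
    returned in row-major order.
    """
    if scale not in (10, 40):
        raise ValueError("tile enumeration is defined for the 10x and 40x scales")
    if not tumor_cells.any():
        warnings.warn("empty tumor mask: no tiles")
        return []
    mask = _mask_at_level(tumor_cells, window, pyramid.downsample[scale])
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    tiles: list[Tile] = []
    for tr in range((r1 - r0) // tile_size):
        for tc in range((c1 - c0) // tile_size):
            rr = r0 + tr * tile_size
            cc = c0 + tc * tile_size
            frac = float(mask[rr:rr + tile_size, cc:cc + tile_size].mean())
            if frac > tissue_fraction_min:
                tiles.append(Tile(
                    image=pyramid.region(scale, rr, cc, tile_size, tile_size),
                    scale=scale, origin=(rr, cc), tissue_fraction=frac))
    if not tiles:
        warnings.warn(f"no qualifying tiles at {scale}x")
    return tiles


def sample_tiles(tiles: list[Tile], cap: int = SAMPLE_CAP,
                 seed: int = 0) -> list[Tile]:
    """Seeded uniform sample without replacement, capped at ``cap`` tiles.

    Returns all tiles when the list is already within the cap; otherwise a
    reproducible subset of exactly ``cap`` tiles, preserving the incoming
    (row-major) order. Sampling an already-sampled list with the same cap is
    the identity.
    """
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if len(tiles) <= cap:
        return list(tiles)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(tiles), size=cap, replace=False))
    return [tiles[i] for i in idx]


# ---------------------------------------------------------------------------
# Reinhard color normalization
# ---------------------------------------------------------------------------

def _rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    from skimage.color import rgb2lab
    return rgb2lab(rgb.astype(np.uint8))


def _lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    from skimage.color import lab2rgb
    rgb = lab2rgb(lab)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def reinhard_stats(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel (mean, sd) of the image in CIELAB, the transfer space."""
    lab = _rgb_to_lab(np.asarray(image))
    flat = lab.reshape(-1, 3)
    return flat.mean(axis=0), flat.std(axis=0)


# default reference: mid-gray stained-tissue statistics in CIELAB
DEFAULT_REFERENCE = (np.array([65.0, 10.0, -5.0]), np.array([12.0, 6.0, 4.0]))


def color_normalize(image: np.ndarray,
                    reference: tuple[np.ndarray, np.ndarray] = DEFAULT_REFERENCE
                    ) -> np.ndarray:
    """Reinhard mean/sd color transfer toward reference CIELAB statistics.

    Each channel is centered, rescaled by the ratio of reference to source
    standard deviation, shifted to the reference mean, and mapped back to
    RGB with clipping. A zero-variance source channel is passed through as a
    pure shift to the reference mean, with a warning.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("color_normalize expects an RGB image")
    ref_mean, ref_sd = reference
    lab = _rgb_to_lab(img)
    flat = lab.reshape(-1, 3)
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0)
    out = np.empty_like(flat)
    for ch in range(3):
        if sd[ch] == 0:
            warnings.warn(f"zero variance in channel {ch}: shifting to reference mean")
            out[:, ch] = ref_mean[ch]
        else:
            out[:, ch] = (flat[:, ch] - mean[ch]) * (ref_sd[ch] / sd[ch]) + ref_mean[ch]
    return _lab_to_rgb(out.reshape(lab.shape))
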