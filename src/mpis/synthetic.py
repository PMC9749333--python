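"""Synthetic fixtures: textured slides, survival cohorts, expression matrices.

The generators emulate the three data layers the pipeline consumes:

* slides containing a textured tumor region distinct from the surrounding
  tissue, on a white (255) scanner background, with exact ground-truth masks;
* survival cohorts whose hazard depends log-linearly on a sparse subset of
  texture features (exponential event and censoring times, so every check
  has a closed form);
* expression matrices with planted group-shifted genes organized into gene
  sets, one of which is enriched in the planted genes.

Every generator is bit-reproducible given its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .histogenomics import GeneSet

__all__ = [
    "TextureParams",
    "ShapeSpec",
    "SyntheticCohortSpec",
    "gen_texture_tile",
    "gen_slide",
    "gen_feature_table",
    "gen_survival_cohort",
    "gen_expression",
    "CLINICAL_COLUMNS",
]

PATTERNS = ("constant", "stripes", "checker", "blobs", "gaussian_field")


@dataclass
class TextureParams:
    """Parameters controlling one synthetic texture.

    ``correlation_length`` is the spatial scale in pixels: the stripe/checker
    period, or the Gaussian smoothing length of the blob and random-field
    patterns. ``blob_density`` is the target coverage fraction of
    low-intensity blobs; it is enforced exactly via the quantile of the
    smoothed field.
    """

    pattern: str = "gaussian_field"
    intensity_low: int = 60
    intensity_high: int = 200
    blob_density: float = 0.3
    correlation_length: float = 8.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if not 0 <= self.intensity_low <= self.intensity_high <= 255:
            raise ValueError("need 0 <= intensity_low <= intensity_high <= 255")
        if not 0.0 <= self.blob_density <= 1.0:
            raise ValueError("blob_density must be in [0, 1]")
        if self.correlation_length < 0 or self.noise_sd < 0:
            raise ValueError("correlation_length and noise_sd must be >= 0")


def gen_texture_tile(params: TextureParams, height: int, width: int) -> np.ndarray:
    """Generate one 8-bit grayscale texture tile, deterministic given the seed."""
    if height < 4 or width < 4:
        raise ValueError("tile dimensions must be >= 4")
    rng = np.random.default_rng(params.seed)
    lo, hi = float(params.intensity_low), float(params.intensity_high)
    period = max(1, int(round(params.correlation_length)))

    if params.pattern == "constant":
        img = np.full((height, width), hi)
    elif params.pattern == "stripes":
        cols = (np.arange(width) // period) % 2
        img = np.where(cols[None, :] == 0, lo, hi) * np.ones((height, 1))
    elif params.pattern == "checker":
        rr = (np.arange(height) // period) % 2
        cc = (np.arange(width) // period) % 2
        img = np.where(rr[:, None] == cc[None, :], lo, hi)
    elif params.pattern == "blobs":
        fieldv = ndimage.gaussian_filter(
            rng.standard_normal((height, width)), sigma=max(params.correlation_length, 1e-9))
        cut = np.quantile(fieldv, params.blob_density)
        img = np.where(fieldv <= cut, lo, hi)
    else:  # gaussian_field
        fieldv = ndimage.gaussian_filter(
            rng.standard_normal((height, width)), sigma=max(params.correlation_length, 1e-9))
        lo_v, hi_v = fieldv.min(), fieldv.max()
        unit = (fieldv - lo_v) / (hi_v - lo_v) if hi_v > lo_v else np.zeros_like(fieldv)
        img = lo + unit * (hi - lo)

    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


@dataclass
class ShapeSpec:
    """A paintable region: disc, ellipse, rectangle or polygon.

    Coordinates are (row, col) at base resolution. Discs/ellipses keep area
    checks analytic; polygons are accepted for irregular regions.
    """

    kind: str = "disc"                      # disc | ellipse | rect | polygon
    center: tuple[float, float] = (0.0, 0.0)
    radius: float = 0.0                     # disc
    radii: tuple[float, float] = (0.0, 0.0)  # ellipse (row, col semi-axes)
    extent: tuple[float, float, float, float] = (0, 0, 0, 0)  # rect r0,c0,r1,c1
    vertices: tuple[tuple[float, float], ...] = ()            # polygon

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        h, w = shape
        rr, cc = np.mgrid[0:h, 0:w]
        if self.kind == "disc":
            if self.radius <= 0:
                return np.zeros(shape, dtype=bool)
            return ((rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2
                    <= self.radius ** 2)
        if self.kind == "ellipse":
            a, b = self.radii
            if a <= 0 or b <= 0:
                return np.zeros(shape, dtype=bool)
            return (((rr - self.center[0]) / a) ** 2
                    + ((cc - self.center[1]) / b) ** 2) <= 1.0
        if self.kind == "rect":
            r0, c0, r1, c1 = self.extent
            return (rr >= r0) & (rr < r1) & (cc >= c0) & (cc < c1)
        if self.kind == "polygon":
            from skimage.draw import polygon2mask
            return polygon2mask(shape, np.asarray(self.vertices))
        raise ValueError(f"unknown shape kind {self.kind!r}")

    def bounds_ok(self, shape: tuple[int, int]) -> bool:
        m = self.mask(shape)
        if not m.any():
            return True
        rows = np.nonzero(m.any(axis=1))[0]
        cols = np.nonzero(m.any(axis=0))[0]
        if self.kind == "disc":
            r, c = self.center
            return (r - self.radius >= 0 and c - self.radius >= 0
                    and r + self.radius < shape[0] and c + self.radius < shape[1])
        return (rows[0] > 0 and cols[0] > 0
                and rows[-1] < shape[0] - 1 and cols[-1] < shape[1] - 1)


def gen_slide(tumor_params: TextureParams, background_params: TextureParams,
              base_size: tuple[int, int], tumor_shape: ShapeSpec,
              tissue_shape: ShapeSpec | None = None,
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paint a synthetic slide: white background, textured tissue and tumor.

    Returns ``(slide, tumor_mask, tissue_mask)`` at base resolution. Tumor
    pixels are drawn from ``tumor_params``, non-tumor tissue from
    ``background_params``, and non-tissue is white (255) so Otsu tissue
    masking sees a genuinely bimodal histogram. Masks align pixelwise with
    the painted regions. The tumor region must lie strictly inside the
    slide bounds.
    """
    h, w = base_size
    if tissue_shape is None:
        margin_r, margin_c = max(2, h // 20), max(2, w // 20)
        tissue_shape = ShapeSpec(kind="rect",
                                 extent=(margin_r, margin_c, h - margin_r, w - margin_c))
    if not tumor_shape.bounds_ok(base_size):
        raise ValueError("tumor shape exceeds slide bounds")
    tumor = tumor_shape.mask(base_size)
    tissue = tissue_shape.mask(base_size) | tumor
    slide = np.full(base_size, 255, dtype=np.uint8)
    bg = gen_texture_tile(background_params, h, w)
    tm = gen_texture_tile(tumor_params, h, w)
    slide[tissue] = bg[tissue]
    slide[tumor] = tm[tumor]
    return slide, tumor, tissue


# ---------------------------------------------------------------------------
# Survival cohorts
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = ("slide_id", "time_months", "event", "age_group", "sex",
                    "smoking", "site", "treatment", "differentiation", "tnm_stage")

# categorical marginals loosely typical of a resectable-LUAD surgical cohort
_CATEGORICALS = {
    "age_group": (("<65", ">=65"), (0.4, 0.6)),
    "sex": (("Male", "Female"), (0.5, 0.5)),
    "smoking": (("Ever", "Never"), (0.35, 0.65)),
    "site": (("Upper/Middle", "Lower"), (0.62, 0.38)),
    "treatment": (("Surg.", "Surg.+Chemo"), (0.6, 0.4)),
    "differentiation": (("G1/G2", "G3/G4"), (0.78, 0.22)),
    "tnm_stage": (("I", "II", "III"), (0.6, 0.22, 0.18)),
}


@dataclass
class SyntheticCohortSpec:
    """Conditions for one synthetic survival cohort.

    Event times are exponential with rate
    ``baseline_hazard_rate * exp(sum_k beta_k z_k + stage_effect * stage_level)``
    where ``z`` are the Z-scored feature values; censoring times are
    exponential(``censoring_rate``) truncated at ``max_follow_up``. The
    default rates (events 1/60 per month, censoring 1/180, 120-month
    follow-up) yield roughly 30% censoring.
    ``stage_effect`` adds a per-level TNM-stage log-hazard (0 for stage I,
    1x for II, 2x for III); it defaults to 0 so feature-recovery checks see
    no omitted covariate.
    """

    n_slides: int = 100
    true_coefficients: dict[str, float] = field(default_factory=dict)
    baseline_hazard_rate: float = 1.0 / 60.0
    censoring_rate: float = 1.0 / 180.0
    max_follow_up: float = 120.0
    stage_effect: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_slides < 2:
            raise ValueError("n_slides must be >= 2")
        if self.baseline_hazard_rate <= 0 or self.censoring_rate <= 0:
            raise ValueError("rates must be > 0")


def gen_feature_table(n_slides: int, feature_ids: list[str],
                      seed: int = 0) -> pd.DataFrame:
    """I.i.d. standard-normal per-slide feature values (slide_id index)."""
    rng = np.random.default_rng(seed)
    ids = [f"S{i:04d}" for i in range(n_slides)]
    return pd.DataFrame(rng.standard_normal((n_slides, len(feature_ids))),
                        index=pd.Index(ids, name="slide_id"), columns=feature_ids)


def gen_survival_cohort(spec: SyntheticCohortSpec,
                        feature_table: pd.DataFrame) -> pd.DataFrame:
    """Survival records driven by a sparse linear signal in the features.

    Returns one row per slide with the clinical-table columns. The recorded
    time is ``min(event_time, censoring_time)`` and ``event`` indicates the
    event came first. Deterministic given the spec's seed.
    """
    missing = [f for f in spec.true_coefficients if f not in feature_table.columns]
    if missing:
        raise ValueError(f"features absent from table: {missing}")
    if len(feature_table) != spec.n_slides:
        raise ValueError("feature_table row count must equal spec.n_slides")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_slides

    lp = np.zeros(n)
    for fid, beta in spec.true_coefficients.items():
        col = feature_table[fid].to_numpy(dtype=float)
        sd = col.std()
        z = (col - col.mean()) / sd if sd > 0 else np.zeros(n)
        lp += beta * z

    cats = {}
    for name, (levels, probs) in _CATEGORICALS.items():
        cats[name] = rng.choice(levels, size=n, p=probs)
    if spec.stage_effect:
        stage_level = pd.Categorical(cats["tnm_stage"],
                                     categories=("I", "II", "III")).codes
        lp = lp + spec.stage_effect * stage_level

    t_event = rng.exponential(1.0 / (spec.baseline_hazard_rate * np.exp(lp)))
    t_cens = np.minimum(rng.exponential(1.0 / spec.censoring_rate, size=n),
                        spec.max_follow_up)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    out = pd.DataFrame({
        "slide_id": feature_table.index.to_numpy(),
        "time_months": time,
        "event": event,
        **cats,
    })
    return out[list(CLINICAL_COLUMNS)]


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

def gen_expression(n_genes: int, groups: pd.Series, n_de: int, shift: float,
                   n_sets: int = 10, set_size: int = 50, seed: int = 0,
                   de_set_fraction: float = 0.8, n_zero_genes: int = 0,
                   ) -> tuple[pd.DataFrame, list[GeneSet], list[str]]:
    """Expression matrix with planted differential genes and gene sets.

    ``groups`` maps sample id -> 'high' / 'low' risk label. Non-differential
    genes are i.i.d. N(5, 1) across all samples; the ``n_de`` planted genes
    are shifted by ``shift`` (in sd units) in the high-risk group. One
    "positive" gene set draws ``de_set_fraction`` of its members from the
    planted genes; the remaining sets are uniform draws. ``n_zero_genes``
    appends all-zero rows for exercising the zero-expression filter.

    Returns ``(matrix genes x samples, gene sets, planted gene ids)``.
    """
    if n_de > n_genes or set_size > n_genes:
        raise ValueError("n_de and set_size must be <= n_genes")
    groups = pd.Series(groups)
    if groups.isna().any():
        raise ValueError(f"missing group label for samples: "
                         f"{list(groups.index[groups.isna()])}")
    bad = set(groups.unique()) - {"high", "low"}
    if bad:
        raise ValueError(f"group labels must be 'high'/'low', got {sorted(bad)}")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    samples = list(groups.index)

    X = rng.normal(5.0, 1.0, size=(n_genes, len(samples)))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    high = (groups.to_numpy() == "high")
    X[np.ix_(de_idx, np.nonzero(high)[0])] += shift
    planted = [genes[i] for i in sorted(de_idx)]

    sets: list[GeneSet] = []
    if n_sets >= 1:
        n_from_de = min(int(round(de_set_fraction * set_size)), n_de)
        members = list(rng.choice(planted, size=n_from_de, replace=False))
        others = [g for g in genes if g not in set(members)]
        members += list(rng.choice(others, size=set_size - n_from_de, replace=False))
        sets.append(GeneSet(name="SET_POSITIVE",
                            description="planted enriched set",
                            genes=tuple(sorted(members))))
    for k in range(1, n_sets):
        members = rng.choice(genes, size=set_size, replace=False)
        sets.append(GeneSet(name=f"SET_{k:03d}", description="random set",
                            genes=tuple(sorted(members))))

    mat = pd.DataFrame(X, index=pd.Index(genes, name="gene"), columns=samples)
    if n_zero_genes:
        zeros = pd.DataFrame(0.0, columns=samples,
                             index=[f"Z{i:05d}" for i in range(n_zero_genes)])
        mat = pd.concat([mat, zeros])
    return mat, sets, planted
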