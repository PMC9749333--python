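"""Feature engine: hand examples, brute-force oracles, catalog structure."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mpis.features import (FIRST_ORDER_NAMES, GLCM_NAMES, GLRLM_ANGLES,
                           GLRLM_NAMES, FeatureDescriptor, QuantizedTile,
                           feature_catalog, first_order_features,
                           glcm_features, glcm_matrix, glrlm_features,
                           glrlm_matrix, quantize, slide_feature_vector,
                           tile_features)
from mpis.synthetic import TextureParams, gen_texture_tile

from conftest import random_masked_tile

# ---------------------------------------------------------------------------
# brute-force oracles (independent of the vectorized implementations)
# ---------------------------------------------------------------------------

_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_oracle(q: QuantizedTile) -> np.ndarray:
    """Count every ordered horizontal pair pixel by pixel."""
    ng = q.n_gray
    P = np.zeros((ng, ng))
    h, w = q.levels.shape
    for r in range(h):
        for c in range(w - 1):
            if q.valid[r, c] and q.valid[r, c + 1]:
                P[q.levels[r, c] - 1, q.levels[r, c + 1] - 1] += 1
    P = P + P.T
    return P / P.sum() if P.sum() else P

def glrlm_oracle(q: QuantizedTile, angle: int) -> np.ndarray:
    """Enumerate runs by walking every line start in the offset direction."""
    dr, dc = _OFFSETS[angle]
    h, w = q.levels.shape
    visited = np.zeros((h, w), dtype=bool)
    runs = []
    # walk from every cell that has no predecessor along (dr, dc)
    for r in range(h):
        for c in range(w):
            pr, pc = r - dr, c - dc
            if 0 <= pr < h and 0 <= pc < w:
                continue  # not a line start
            rr, cc = r, c
            current = None
            length = 0
            while 0 <= rr < h and 0 <= cc < w:
                if q.valid[rr, cc] and q.levels[rr, cc] == current:
                    length += 1
                else:
                    if length:
                        runs.append((current, length))
                    if q.valid[rr, cc]:
                        current, length = int(q.levels[rr, cc]), 1
                    else:
                        current, length = None, 0
                rr += dr
                cc += dc
            if length:
                runs.append((current, length))
    max_len = max((l for _, l in runs), default=1)
    p = np.zeros((q.n_gray, max_len))
    for lvl, ln in runs:
        p[lvl - 1, ln - 1] += 1
    return p


def _features_from_matrix_glcm(P, ng):
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, ng + 1)[None, :]
    pi = P.sum(axis=1)
    mu = (np.arange(1, ng + 1) * pi).sum()
    sig2 = ((np.arange(1, ng + 1) - mu) ** 2 * pi).sum()
    nz = P[P > 0]
    return {
        "ASM": (P ** 2).sum(),
        "contrast": (((i - j) ** 2) * P).sum(),
        "correlation": ((i - mu) * (j - mu) * P).sum() / sig2 if sig2 > 0 else 0.0,
        "dissimilarity": (np.abs(i - j) * P).sum(),
        "homogeneity": (P / (1 + (i - j) ** 2)).sum(),
        "entropy": -(nz * np.log2(nz)).sum(),
        "max_probability": P.max(),
    }


def _features_from_matrix_glrlm(p, n_p):
    n_r = p.sum()
    i = np.arange(1, p.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, p.shape[1] + 1, dtype=float)[None, :]
    return {
        "SRE": (p / j ** 2).sum() / n_r,
        "LRE": (p * j ** 2).sum() / n_r,
        "GLN": (p.sum(axis=1) ** 2).sum() / n_r,
        "RLN": (p.sum(axis=0) ** 2).sum() / n_r,
        "RP": n_r / n_p,
        "LGLRE": (p / i ** 2).sum() / n_r,
        "HGLRE": (p * i ** 2).sum() / n_r,
        "SRLGLE": (p / (i ** 2 * j ** 2)).sum() / n_r,
        "SRHGLE": (p * i ** 2 / j ** 2).sum() / n_r,
        "LRLGLE": (p * j ** 2 / i ** 2).sum() / n_r,
        "LRHGLE": (p * i ** 2 * j ** 2).sum() / n_r,
    }


# ---------------------------------------------------------------------------
# quantization
# ---------------------------------------------------------------------------

def test_quantize_bin_edges_and_per_pixel_oracle():
    rng = np.random.default_rng(0)
    tile = rng.integers(0, 256, size=(12, 9)).astype(np.uint8)
    q = quantize(tile, n_gray=16)
    # independent per-pixel recomputation of the bin formula
    expected = np.floor(tile.astype(float) * 16 / 256).astype(int) + 1
    assert np.array_equal(q.levels, expected)
    assert quantize(np.array([[0, 255], [0, 255]], dtype=np.uint8)).levels.tolist() \
        == [[1, 16], [1, 16]]


def test_quantize_rejects_degenerate_levels():
    with pytest.raises(ValueError):
        quantize(np.zeros((4, 4), dtype=np.uint8), n_gray=1)


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

def test_first_order_constant_tile_guards():
    f = first_order_features(np.full((6, 6), 100, dtype=np.uint8))
    assert f["Mean"] == 100 and f["Range"] == 0
    assert f["Entropy"] == 0 and f["Uniformity"] == 1
    assert f["Skewness"] == 0 and f["Kurtosis"] == 0


def test_first_order_percentile_linear_interpolation():
    vals = np.arange(10, 101, 10, dtype=np.uint8).reshape(2, 5)
    f = first_order_features(vals)
    # rank position 0.1*(n-1) = 0.9 between 10 and 20 -> 19
    assert f["Percentile_10th"] == pytest.approx(19.0)
    assert f["Percentile_90th"] == pytest.approx(91.0)


def test_first_order_uniform_histogram_entropy():
    # one pixel in each of the 16 bins -> 4 bits
    vals = (np.arange(16) * 16).astype(np.uint8).reshape(4, 4)
    assert first_order_features(vals)["Entropy"] == pytest.approx(4.0)


def test_first_order_against_independent_formulas():
    rng = np.random.default_rng(7)
    x = rng.integers(0, 256, size=(20, 20)).astype(np.uint8)
    f = first_order_features(x)
    flat = x.astype(float).ravel()
    assert f["Variance"] == pytest.approx(flat.var())
    assert f["Energy"] == pytest.approx((flat ** 2).sum())
    assert f["RMS"] == pytest.approx(np.sqrt((flat ** 2).mean()))
    assert f["MAD"] == pytest.approx(np.abs(flat - flat.mean()).mean())
    z = (flat - flat.mean()) / flat.std()
    assert f["Skewness"] == pytest.approx((z ** 3).mean())
    assert f["Kurtosis"] == pytest.approx((z ** 4).mean())


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def test_glcm_constant_tile_closed_forms():
    q = quantize(np.full((5, 5), 77, dtype=np.uint8))
    f = glcm_features(q)
    assert f["ASM"] == 1 and f["contrast"] == 0 and f["dissimilarity"] == 0
    assert f["entropy"] == 0 and f["max_probability"] == 1


def test_glcm_alternating_stripes_hand_count():
    # 4x4, columns 0/255/0/255: 12 ordered pairs, all (1,16) or (16,1)
    tile = np.tile(np.array([0, 255, 0, 255], dtype=np.uint8), (4, 1))
    f = glcm_features(quantize(tile))
    assert f["ASM"] == pytest.approx(0.5)
    assert f["contrast"] == pytest.approx(225.0)
    assert f["dissimilarity"] == pytest.approx(15.0)
    assert f["entropy"] == pytest.approx(1.0)
    P = glcm_matrix(quantize(tile))
    assert P[0, 15] == pytest.approx(0.5) and P[15, 0] == pytest.approx(0.5)


def test_glcm_no_valid_pair_is_missing():
    q = QuantizedTile(levels=np.ones((1, 3), dtype=int),
                      valid=np.array([[True, False, True]]), n_gray=16)
    assert all(np.isnan(v) for v in glcm_features(q).values())


def test_glcm_matrix_is_symmetric_and_normalized():
    rng = np.random.default_rng(3)
    for _ in range(20):
        q = random_masked_tile(rng)
        P = glcm_matrix(q)
        if P.sum() == 0:
            continue
        assert P.sum() == pytest.approx(1.0)
        assert np.allclose(P, P.T)


def test_glcm_direction_equivariance():
    """Angle-0 features of the transpose equal vertical-offset features."""
    rng = np.random.default_rng(11)
    tile = rng.integers(0, 256, size=(10, 10)).astype(np.uint8)
    q = quantize(tile)
    qt = quantize(tile.T)
    # vertical pairs of the original = horizontal pairs of the transpose
    f_t = glcm_features(qt)
    ng = q.n_gray
    P = np.zeros((ng, ng))
    for r in range(9):
        for c in range(10):
            P[q.levels[r, c] - 1, q.levels[r + 1, c] - 1] += 1
    P = P + P.T
    P /= P.sum()
    expected = _features_from_matrix_glcm(P, ng)
    for name in GLCM_NAMES:
        assert f_t[name] == pytest.approx(expected[name], abs=1e-12)


# ---------------------------------------------------------------------------
# GLRLM
# ---------------------------------------------------------------------------

def test_glrlm_constant_tile_closed_forms():
    q = quantize(np.full((8, 8), 100, dtype=np.uint8))
    f = glrlm_features(q, 0)
    assert f["SRE"] == pytest.approx(1 / 64)
    assert f["LRE"] == pytest.approx(64.0)
    assert f["RP"] == pytest.approx(1 / 8)


def test_glrlm_single_row_hand_runs():
    lv = np.array([[1, 1, 2, 2, 2, 3]])
    q = QuantizedTile(levels=lv, valid=np.ones_like(lv, dtype=bool), n_gray=16)
    f = glrlm_features(q, 0)
    # runs (1,2),(2,3),(3,1) -> SRE = (1/3)(1/4 + 1/9 + 1)
    assert f["SRE"] == pytest.approx((1 / 4 + 1 / 9 + 1) / 3)
    assert f["RP"] == pytest.approx(3 / 6)


@pytest.mark.parametrize("angle", GLRLM_ANGLES)
def test_glrlm_matches_bruteforce_on_random_masked_tiles(angle):
    rng = np.random.default_rng(100 + angle)
    for _ in range(50):
        q = random_masked_tile(rng)
        ours = glrlm_features(q, angle)
        p = glrlm_oracle(q, angle)
        expected = _features_from_matrix_glrlm(p, int(q.valid.sum()))
        for name in GLRLM_NAMES:
            assert ours[name] == pytest.approx(expected[name], abs=1e-12), \
                (name, q.levels, q.valid)


def test_glcm_matches_bruteforce_on_random_masked_tiles():
    rng = np.random.default_rng(200)
    for _ in range(50):
        q = random_masked_tile(rng)
        P = glcm_oracle(q)
        ours = glcm_features(q)
        if P.sum() == 0:
            assert all(np.isnan(v) for v in ours.values())
            continue
        expected = _features_from_matrix_glcm(P, q.n_gray)
        for name in GLCM_NAMES:
            assert ours[name] == pytest.approx(expected[name], abs=1e-12)


@pytest.mark.parametrize("angle", GLRLM_ANGLES)
def test_glrlm_pixel_conservation_and_ranges(angle):
    rng = np.random.default_rng(40 + angle)
    for _ in range(20):
        q = random_masked_tile(rng)
        p = glrlm_matrix(q, angle)
        j = np.arange(1, p.shape[1] + 1)
        assert (p * j).sum() == int(q.valid.sum())
        f = glrlm_features(q, angle)
        assert 0 < f["SRE"] <= 1
        assert f["LRE"] >= 1
        assert 0 < f["RP"] <= 1


def test_stripe_frequency_monotonicity():
    """Finer stripes raise GLCM contrast and shorten horizontal runs."""
    contrasts, lres = [], []
    for period in (16, 8, 4, 2, 1):
        tile = gen_texture_tile(
            TextureParams(pattern="stripes", intensity_low=0,
                          intensity_high=255, correlation_length=period,
                          noise_sd=0, seed=0), 64, 64)
        q = quantize(tile)
        contrasts.append(glcm_features(q)["contrast"])
        lres.append(glrlm_features(q, 0)["LRE"])
    assert all(a < b for a, b in zip(contrasts, contrasts[1:]))
    assert all(a > b for a, b in zip(lres, lres[1:]))


# ---------------------------------------------------------------------------
# catalog and aggregation
# ---------------------------------------------------------------------------

def test_catalog_counts_and_structure():
    cat = feature_catalog()
    assert len(cat) == 204
    one_scale = feature_catalog(scales=(10,))
    assert len(one_scale) == 68
    fams = {}
    for d in one_scale:
        fams[d.family] = fams.get(d.family, 0) + 1
    assert fams == {"firstorder": 17, "glcm": 7, "glrlm": 44}
    assert len(FIRST_ORDER_NAMES) == 17 and len(GLCM_NAMES) == 7
    assert len(GLRLM_NAMES) == 11


def test_catalog_resolves_signature_feature_ids():
    ids = {d.canonical_id: d for d in feature_catalog()}
    eight = ["glrlm_SRLGLE_90_2.5", "glrlm_SRLGLE_90_40",
             "glcm_dissimilarity_0_2.5", "Kurtosis_10",
             "glrlm_LRHGLE_90_2.5", "glrlm_SRE_0_40", "glcm_ASM_0_2.5",
             "Percentile_10th_40"]
    for cid in eight:
        assert cid in ids
    d = ids["glcm_ASM_0_2.5"]
    assert (d.family, d.name, d.angle, d.scale) == ("glcm", "ASM", 0, 2.5)
    assert FeatureDescriptor.parse("glrlm_SRLGLE_90_2.5").angle == 90


def test_slide_vector_aggregates_mean_across_tiles():
    rng = np.random.default_rng(5)
    t1 = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
    t2 = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
    region = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
    vec = slide_feature_vector("s", {2.5: [(region, None)],
                                     10: [(t1, None)],
                                     40: [(t1, None), (t2, None)]})
    assert vec.complete
    f1 = tile_features(t1, scale=40)
    f2 = tile_features(t2, scale=40)
    assert vec.values["Kurtosis_40"] == pytest.approx(
        (f1["Kurtosis_40"] + f2["Kurtosis_40"]) / 2)
    # single-tile scales equal the per-tile features
    assert vec.values["Kurtosis_10"] == pytest.approx(
        tile_features(t1, scale=10)["Kurtosis_10"])


def test_slide_vector_missing_scale_is_incomplete():
    rng = np.random.default_rng(6)
    t1 = rng.integers(0, 256, size=(16, 16)).astype(np.uint8)
    vec = slide_feature_vector("s", {2.5: [(t1, None)], 10: [(t1, None)],
                                     40: []})
    assert not vec.complete
    assert "Kurtosis_40" in vec.missing_ids()


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_glcm_sum_one_property(seed):
    q = random_masked_tile(np.random.default_rng(seed))
    P = glcm_matrix(q)
    assert P.sum() == pytest.approx(1.0) or P.sum() == 0
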