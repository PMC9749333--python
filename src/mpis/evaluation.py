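"""Study-condition benchmark runs: recovery, calibration and null controls.

Each function here executes one self-contained experiment at the package's
reference conditions -- planted-signal signature recovery, log-rank size,
Cox hazard-ratio recovery, concordance/AUC cross-checks, model-comparison
structure, and the histo-genomic null and power controls -- and returns the
measured quantities. They are consumed by the acceptance script and the
acceptance test suite; the brute-force texture oracles in this module are
deliberately naive re-implementations kept independent of the vectorized
feature engine they validate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import features as mfeat
from . import histogenomics as mhg
from . import signature as msig
from . import survival as msurv
from . import synthetic as msyn
from . import tiling as mtile

__all__ = [
    "catalog_structure",
    "tile_sampler_check",
    "texture_oracle_equivalence",
    "signature_recovery",
    "survival_calibration",
    "model_comparison",
    "histogenomic_controls",
]


# ---------------------------------------------------------------------------
# structure and sampling
# ---------------------------------------------------------------------------

def catalog_structure() -> dict:
    """Counts and signature-id resolution of the descriptor catalog."""
    cat = mfeat.feature_catalog()
    per_scale = mfeat.feature_catalog(scales=(10,))
    fams = {"firstorder": 0, "glcm": 0, "glrlm": 0}
    for d in per_scale:
        fams[d.family] += 1
    eight = ["glrlm_SRLGLE_90_2.5", "glrlm_SRLGLE_90_40",
             "glcm_dissimilarity_0_2.5", "Kurtosis_10",
             "glrlm_LRHGLE_90_2.5", "glrlm_SRE_0_40", "glcm_ASM_0_2.5",
             "Percentile_10th_40"]
    ids = {d.canonical_id for d in cat}
    return {
        "total": len(cat),
        "per_scale": len(per_scale),
        "firstorder": fams["firstorder"],
        "glcm": fams["glcm"],
        "glrlm": fams["glrlm"],
        "signature_ids_resolved": sum(i in ids for i in eight),
    }


def tile_sampler_check(seed: int = 0, n_tiles: int = 350,
                       cap: int = 200) -> dict:
    """Seeded sampling of an over-cap tile list."""
    tiles = [mtile.Tile(image=np.zeros((2, 2), np.uint8), scale=40,
                        origin=(0, i), tissue_fraction=1.0)
             for i in range(n_tiles)]
    a = mtile.sample_tiles(tiles, cap=cap, seed=seed)
    b = mtile.sample_tiles(tiles, cap=cap, seed=seed)
    return {"n_sampled": len(a),
            "reproducible": [t.origin for t in a] == [t.origin for t in b]}


# ---------------------------------------------------------------------------
# texture oracles
# ---------------------------------------------------------------------------

def _glcm_bruteforce(q: mfeat.QuantizedTile) -> dict:
    ng = q.n_gray
    P = np.zeros((ng, ng))
    h, w = q.levels.shape
    for r in range(h):
        for c in range(w - 1):
            if q.valid[r, c] and q.valid[r, c + 1]:
                P[q.levels[r, c] - 1, q.levels[r, c + 1] - 1] += 1
    P = P + P.T
    if P.sum() == 0:
        return {k: float("nan") for k in mfeat.GLCM_NAMES}
    P /= P.sum()
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, ng + 1)[None, :]
    pi = P.sum(axis=1)
    mu = (np.arange(1, ng + 1) * pi).sum()
    sig2 = ((np.arange(1, ng + 1) - mu) ** 2 * pi).sum()
    nz = P[P > 0]
    return {
        "ASM": float((P ** 2).sum()),
        "contrast": float((((i - j) ** 2) * P).sum()),
        "correlation": float(((i - mu) * (j - mu) * P).sum() / sig2)
        if sig2 > 0 else 0.0,
        "dissimilarity": float((np.abs(i - j) * P).sum()),
        "homogeneity": float((P / (1 + (i - j) ** 2)).sum()),
        "entropy": float(-(nz * np.log2(nz)).sum()),
        "max_probability": float(P.max()),
    }


def _glrlm_bruteforce(q: mfeat.QuantizedTile, angle: int) -> dict:
    dr, dc = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}[angle]
    h, w = q.levels.shape
    runs = []
    for r in range(h):
        for c in range(w):
            if 0 <= r - dr < h and 0 <= c - dc < w:
                continue
            rr, cc, cur, ln = r, c, None, 0
            while 0 <= rr < h and 0 <= cc < w:
                if q.valid[rr, cc] and q.levels[rr, cc] == cur:
                    ln += 1
                else:
                    if ln:
                        runs.append((cur, ln))
                    cur, ln = (int(q.levels[rr, cc]), 1) if q.valid[rr, cc] \
                        else (None, 0)
                rr += dr
                cc += dc
            if ln:
                runs.append((cur, ln))
    if not runs:
        return {k: float("nan") for k in mfeat.GLRLM_NAMES}
    n_r = len(runs)
    n_p = int(q.valid.sum())
    out = dict.fromkeys(mfeat.GLRLM_NAMES, 0.0)
    gl_tot: dict[int, float] = {}
    rl_tot: dict[int, float] = {}
    for i, j in runs:
        out["SRE"] += 1 / j ** 2
        out["LRE"] += j ** 2
        out["LGLRE"] += 1 / i ** 2
        out["HGLRE"] += i ** 2
        out["SRLGLE"] += 1 / (i ** 2 * j ** 2)
        out["SRHGLE"] += i ** 2 / j ** 2
        out["LRLGLE"] += j ** 2 / i ** 2
        out["LRHGLE"] += i ** 2 * j ** 2
        gl_tot[i] = gl_tot.get(i, 0.0) + 1
        rl_tot[j] = rl_tot.get(j, 0.0) + 1
    for k in ("SRE", "LRE", "LGLRE", "HGLRE", "SRLGLE", "SRHGLE",
              "LRLGLE", "LRHGLE"):
        out[k] /= n_r
    out["GLN"] = sum(v ** 2 for v in gl_tot.values()) / n_r
    out["RLN"] = sum(v ** 2 for v in rl_tot.values()) / n_r
    out["RP"] = n_r / n_p
    return out


def texture_oracle_equivalence(n_tiles: int = 200, seed: int = 0) -> dict:
    """Max |implementation - brute force| over random masked tiles <= 8x8,
    plus the constant-tile closed forms."""
    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_tiles):
        h = int(rng.integers(2, 9))
        w = int(rng.integers(2, 9))
        levels = rng.integers(1, 17, size=(h, w))
        valid = rng.random((h, w)) < 0.8
        if not valid.any():
            valid[0, 0] = True
        q = mfeat.QuantizedTile(levels=levels, valid=valid, n_gray=16)
        got = mfeat.glcm_features(q)
        want = _glcm_bruteforce(q)
        for k in mfeat.GLCM_NAMES:
            if np.isnan(want[k]):
                assert np.isnan(got[k])
            else:
                max_err = max(max_err, abs(got[k] - want[k]))
        for angle in mfeat.GLRLM_ANGLES:
            got = mfeat.glrlm_features(q, angle)
            want = _glrlm_bruteforce(q, angle)
            for k in mfeat.GLRLM_NAMES:
                max_err = max(max_err, abs(got[k] - want[k]))
    # closed forms on a constant W x W tile
    W = 8
    q = mfeat.quantize(np.full((W, W), 100, dtype=np.uint8))
    glcm = mfeat.glcm_features(q)
    glrlm = mfeat.glrlm_features(q, 0)
    closed = max(abs(glcm["ASM"] - 1.0), abs(glcm["contrast"]),
                 abs(glrlm["SRE"] - 1 / W ** 2), abs(glrlm["LRE"] - W ** 2),
                 abs(glrlm["RP"] - 1 / W))
    return {"max_abs_error": max_err, "closed_form_error": closed,
            "n_tiles": n_tiles}


# ---------------------------------------------------------------------------
# signature recovery
# ---------------------------------------------------------------------------

def signature_recovery(n: int = 500, n_seeds: int = 20, seed: int = 0,
                       folds: int = 10) -> dict:
    """LASSO-Cox planted-feature recovery and risk-group separation.

    For each replicate: 204 i.i.d. features, a 3-feature linear hazard with
    |beta| = 1, ~30-40% censoring; fit the signature with k-fold CV, record
    whether the selected set contains all planted features and whether the
    median-cutoff groups separate at log-rank P < 0.001.
    """
    ids = [d.canonical_id for d in mfeat.feature_catalog()]
    rng = np.random.default_rng(seed)
    superset = 0
    strong_split = 0
    for r in range(n_seeds):
        s1, s2, s3 = rng.integers(0, 2 ** 31 - 1, size=3)
        planted_idx = np.random.default_rng(s1).choice(len(ids), 3,
                                                       replace=False)
        planted = {ids[i]: b for i, b in zip(planted_idx, (1.0, -1.0, 1.0))}
        spec = msyn.SyntheticCohortSpec(n_slides=n, true_coefficients=planted,
                                        seed=int(s2))
        table = msyn.gen_feature_table(n, ids, seed=int(s3))
        cohort = msyn.gen_survival_cohort(spec, table)
        res = msig.TextureSignatureModel(table, cohort).fit(
            folds=folds, seed=int(s1) % 10 ** 6)
        if set(planted) <= set(res.params.index):
            superset += 1
        rec = cohort.copy()
        rec["risk_group"] = res.risk_groups.reindex(rec["slide_id"]).to_numpy()
        if rec["risk_group"].nunique() == 2:
            _, p = msurv.logrank_test(rec)
            if p < 1e-3:
                strong_split += 1
    return {"recovery_rate": superset / n_seeds,
            "logrank_power": strong_split / n_seeds,
            "n": n, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# survival calibration
# ---------------------------------------------------------------------------

def survival_calibration(seed: int = 0, n_null: int = 500,
                         n_cox: int = 2000) -> dict:
    """Log-rank size, Cox HR recovery, C-index and AUC cross-checks."""
    rng = np.random.default_rng(seed)

    # log-rank type I error on null cohorts of n=100
    rejections = 0
    for r in range(n_null):
        rs = np.random.default_rng(rng.integers(0, 2 ** 31 - 1))
        t = rs.exponential(60, 100)
        c = np.minimum(rs.exponential(180, 100), 120)
        rec = pd.DataFrame({"time_months": np.minimum(t, c),
                            "event": (t <= c).astype(int),
                            "risk_group": rs.integers(0, 2, 100)})
        if rec["risk_group"].nunique() < 2 or rec["event"].sum() == 0:
            continue
        _, p = msurv.logrank_test(rec)
        rejections += p < 0.05
    type1 = rejections / n_null

    # Cox recovery of a true hazard ratio of 2
    rs = np.random.default_rng(rng.integers(0, 2 ** 31 - 1))
    g = rs.integers(0, 2, n_cox).astype(float)
    t_ev = rs.exponential(1 / (0.02 * np.exp(np.log(2.0) * g)))
    t_c = np.minimum(rs.exponential(120, n_cox), 120.0)
    rec = pd.DataFrame({"time_months": np.minimum(t_ev, t_c),
                        "event": (t_ev <= t_c).astype(int), "grp": g})
    hr = float(msurv.cox_fit(rec, ["grp"]).summary.loc["grp", "hr"])

    # C-index vs exhaustive pair enumeration on a toy set
    t = np.array([2.0, 4.0, 3.0, 5.0, 1.0])
    e = np.array([1, 0, 1, 1, 1])
    s = np.array([0.9, 0.1, 0.4, 0.2, 0.7])
    num = den = 0.0
    for i in range(5):
        for j in range(5):
            if t[i] < t[j] and e[i] == 1:
                den += 1
                num += 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
    toy = pd.DataFrame({"time_months": t, "event": e})
    got, _ = msurv.c_index(toy, pd.Series(s, index=toy.index), ci=False)
    cindex_err = abs(got - num / den)

    # uncensored time-dependent AUC vs plain ROC AUC
    from sklearn.metrics import roc_auc_score
    rs = np.random.default_rng(rng.integers(0, 2 ** 31 - 1))
    score = rs.standard_normal(400)
    t = rs.exponential(1 / (0.02 * np.exp(score)))
    rec = pd.DataFrame({"time_months": t, "event": 1})
    auc, _ = msurv.time_dependent_auc(rec, pd.Series(score, index=rec.index),
                                      horizon=60.0)
    plain = roc_auc_score((t <= 60.0).astype(int), score)
    return {"logrank_type1": type1, "cox_hr_estimate": hr,
            "cindex_oracle_abs_err": float(cindex_err),
            "auc_vs_roc_abs_err": float(abs(auc - plain)),
            "n_null": n_null, "n_cox": n_cox}


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def model_comparison(n: int = 300, n_seeds: int = 20, seed: int = 0) -> dict:
    """Full (stage + signature score) vs clinical (stage) model structure.

    The hazard carries both a TNM-stage effect and a planted texture-score
    effect; per replicate both Cox models are fitted and compared on
    C-index, AIC and the likelihood-ratio test.
    """
    rng = np.random.default_rng(seed)
    ids = ["f1", "f2", "f3"]
    cindex_wins = aic_wins = lrt_sig = 0
    for r in range(n_seeds):
        s1, s2 = rng.integers(0, 2 ** 31 - 1, size=2)
        spec = msyn.SyntheticCohortSpec(
            n_slides=n, true_coefficients={"f1": 1.0}, stage_effect=0.7,
            seed=int(s1))
        table = msyn.gen_feature_table(n, ids, seed=int(s2))
        cohort = msyn.gen_survival_cohort(spec, table).set_index("slide_id")
        z = (table["f1"] - table["f1"].mean()) / table["f1"].std()
        cohort["signature_score"] = z.reindex(cohort.index).to_numpy()
        clinical = msurv.cox_fit(cohort, ["tnm_stage"])
        full = msurv.cox_fit(cohort, ["tnm_stage", "signature_score"])
        c_clin, _ = msurv.c_index(
            cohort, clinical.predict_partial_hazard_order(cohort), ci=False)
        c_full, _ = msurv.c_index(
            cohort, full.predict_partial_hazard_order(cohort), ci=False)
        _, p = msurv.likelihood_ratio_test(full, clinical)
        cindex_wins += c_full > c_clin
        aic_wins += full.aic < clinical.aic
        lrt_sig += p < 0.05
    return {"cindex_win_rate": cindex_wins / n_seeds,
            "aic_win_rate": aic_wins / n_seeds,
            "lrt_significant_rate": lrt_sig / n_seeds,
            "n": n, "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# histo-genomics controls
# ---------------------------------------------------------------------------

def histogenomic_controls(seed: int = 0, n_seeds: int = 20) -> dict:
    """BH hand value, exact ORA tail, planted-set ranking and null control."""
    from math import comb

    bh = mhg.bh_adjust([0.01, 0.02, 0.03, 0.04])
    bh_err = float(np.max(np.abs(bh - 0.04)))

    universe = [f"g{i}" for i in range(100)]
    degs = universe[:10]
    members = tuple(universe[:5] + universe[50:55])
    out = mhg.overrepresentation_test(degs, universe,
                                      [mhg.GeneSet("s", "d", members)])
    tail = sum(comb(10, k) * comb(90, 10 - k) for k in range(5, 11)) \
        / comb(100, 10)
    ora_err = float(abs(out.loc["s", "pvalue"] - tail))

    # ssGSEA rank invariance
    rng = np.random.default_rng(seed)
    mat = pd.DataFrame(rng.uniform(1, 10, size=(40, 6)),
                       index=[f"g{i}" for i in range(40)])
    sets = [mhg.GeneSet("a", "d", tuple(f"g{i}" for i in range(8))),
            mhg.GeneSet("b", "d", tuple(f"g{i}" for i in range(30, 40)))]
    rank_invariant = bool(np.allclose(mhg.ssgsea_scores(mat, sets),
                                      mhg.ssgsea_scores(mat ** 2, sets)))

    def _groups(n_per):
        return pd.Series(["high"] * n_per + ["low"] * n_per,
                         index=[f"P{i:03d}" for i in range(2 * n_per)])

    # planted enriched set ranks first among sets (DEG -> ORA route)
    ranked_first = 0
    for r in range(n_seeds):
        s = int(rng.integers(0, 2 ** 31 - 1))
        mat_r, sets_r, _ = msyn.gen_expression(
            1000, _groups(50), n_de=50, shift=2.0, n_sets=10, set_size=40,
            seed=s)
        deg = mhg.deg_wilcoxon(mat_r, _groups(50))
        ora = mhg.overrepresentation_test(
            list(deg.index[deg["significant"]]), list(mat_r.index), sets_r)
        ranked_first += ora["pvalue"].idxmin() == "SET_POSITIVE"

    # full null control: no significant sets with shift = 0
    null_clean = 0
    for r in range(n_seeds):
        s = int(rng.integers(0, 2 ** 31 - 1))
        mat_r, sets_r, _ = msyn.gen_expression(
            500, _groups(30), n_de=25, shift=0.0, n_sets=10, set_size=30,
            seed=s)
        deg = mhg.deg_wilcoxon(mat_r, _groups(30))
        ora = mhg.overrepresentation_test(
            list(deg.index[deg["significant"]]), list(mat_r.index), sets_r)
        null_clean += int(ora["significant"].sum() == 0)

    return {"bh_hand_abs_err": bh_err, "ora_tail_abs_err": ora_err,
            "ssgsea_rank_invariant": rank_invariant,
            "planted_set_first_rate": ranked_first / n_seeds,
            "null_clean_rate": null_clean / n_seeds,
            "n_seeds": n_seeds}
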