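# mpis — multi-scale pathology image texture signatures

`mpis` builds a prognostic **multi-scale pathology image texture signature
(MPIS)** from hematoxylin–eosin whole-slide images and evaluates it with the
standard survival-analysis toolkit. It is aimed at computational-pathology
and biostatistics researchers who want an interpretable, fully classical
(non-deep-learning) pipeline from masked histology images to risk
stratification and histo-genomic association.

## What the pipeline does

1. **Tumor segmentation** — Otsu tissue masking, a non-overlapping 224 × 224
   sliding window scored by a pluggable patch classifier (a logistic
   darkness scorer by default; any callable `patch -> [0, 1]` plugs in),
   Otsu binarization of the probability heatmap, and retention of the
   largest connected region as the tumor mask.
2. **Multi-scale tiling** — the whole tumor region at 2.5×, and
   non-overlapping 1024 × 1024 tiles at 10× and 40× (downsample factors
   16/4/1) keeping tiles with > 75 % tumor tissue; at 40× a seeded uniform
   sample caps the count at 200 tiles per slide. Reinhard color
   normalization is available for RGB tiles.
3. **Texture features** — a fixed catalog of 204 descriptors per slide:
   17 first-order statistics, 7 GLCM features (θ = 0°, d = 1, symmetrized),
   and 11 GLRLM features at each of θ ∈ {0°, 45°, 90°, 135°}, i.e. 68 per
   scale × 3 scales, with 16 equal-width gray levels over [0, 255].
4. **Signature** — Z-scoring fitted on the discovery cohort, LASSO-penalized
   Cox partial likelihood with tenfold cross-validated deviance to choose
   the penalty, the score `MPIS = Σ_k β_k z_k`, and the discovery-set median
   as the fixed high/low-risk cutoff (strictly greater ⇒ high risk).
5. **Survival statistics** — Kaplan–Meier, log-rank, univariable Cox screen
   at P < 0.05, backward AIC-stepwise multivariable Cox (Efron ties),
   likelihood-ratio model comparison, Harrell's C-index with bootstrap CI,
   and IPCW time-dependent AUC at a 60-month horizon.
6. **Histo-genomics** — zero-expression filtering, Wilcoxon rank-sum DEGs
   with Benjamini–Hochberg control, hypergeometric over-representation of
   user-supplied gene sets (GMT), per-sample ssGSEA scores (α = 0.25), and
   Wilcoxon association of pathway scores with texture features.

A first-class synthetic-data module generates textured slides with exact
ground-truth masks, survival cohorts whose hazard is log-linear in a sparse
subset of the texture features (exponential event and censoring times), and
expression matrices with planted differential genes — so the whole pipeline
is testable end-to-end without any clinical data.

## Worked example

Fit a signature on a synthetic cohort whose hazard is driven by three
texture features (|β| = 1 each), then stratify and test the split:

```python
from mpis.features import feature_catalog
from mpis.synthetic import SyntheticCohortSpec, gen_feature_table, gen_survival_cohort
from mpis.signature import TextureSignatureModel
from mpis.survival import logrank_test, c_index

ids = [d.canonical_id for d in feature_catalog()]
planted = {"glrlm_SRLGLE_90_2.5": 1.0, "Kurtosis_10": -1.0,
           "Percentile_10th_40": 1.0}
spec = SyntheticCohortSpec(n_slides=400, true_coefficients=planted, seed=7)
features = gen_feature_table(400, ids, seed=8)
cohort = gen_survival_cohort(spec, features)

res = TextureSignatureModel(features, cohort).fit(folds=10, seed=0)
print(res.summary())
```

The summary starts:

```
Texture signature (LASSO-Cox)
==============================================
features selected : 24 / 204 usable
penalty lambda    : 0.0565538
cv folds / seed   : 10 / 0
median cutoff     : -0.01166
high-risk fraction: 0.500
----------------------------------------------
feature                                 coef
...
glrlm_SRLGLE_90_2.5                  0.67996
Kurtosis_10                         -0.81555
Percentile_10th_40                   0.79989
...
```

The three planted features carry by far the largest coefficients (the
remaining selections are small-coefficient noise the LASSO has not fully
shrunk away). Stratifying at the median cutoff and testing the split:

```python
rec = cohort.assign(risk_group=res.risk_groups.reindex(cohort["slide_id"]).to_numpy())
print(logrank_test(rec))                       # (210.7, 9.9e-48)
print(c_index(rec, res.scores.reindex(rec["slide_id"])))  # 0.824 (0.802-0.848)
```

so the high-risk group has sharply worse survival (log-rank χ² = 210.7,
P ≈ 1e-47) and the continuous score discriminates well (C-index 0.824).

A `mpis` command-line tool wraps each stage (`simulate`, `segment`,
`features`, `fit`, `score`, `survival`, `histogenomics`, `run-all`); see
`mpis --help`.

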