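# Methods

This note documents the models, conventions and numerical choices behind
`mpis`, and what the synthetic experiments do and do not demonstrate.

## Segmentation

Tissue masking thresholds the 256-bin gray histogram with Otsu's criterion
(maximal between-class variance; classes `gray <= t` / `gray > t`; ties
broken toward the smallest qualifying threshold). Pixels at or below the
threshold are tissue — this presumes the dominant histogram split is
stained-tissue-versus-white-background. On slides where the tumor/stroma
contrast exceeds the tissue/background contrast the tissue mask can
under-cover; this only drops background windows from patch scoring and does
not harm the tumor mask. A single-valued histogram is flagged degenerate
and maps to an all-tissue mask (or empty, if the constant is white).

Patch scoring slides a non-overlapping `window x window` grid (default
224 px at base magnification) in row-major order with 0-based, half-open
coordinates. Edge windows that do not fully fit are discarded; windows with
no tissue pixel score 0 without calling the classifier. The classifier is
an arbitrary callable `patch -> [0, 1]`; the default is a logistic function
of mean patch darkness relative to a white reference (steepness 0.1/gray
level), adequate whenever the tumor is darker than its surroundings. A
trained model can be plugged in without touching the rest of the pipeline.

The heatmap is binarized by Otsu over a 256-bin quantization of [0, 1] and
the largest connected component retained. Connectivity is 8 by default
(4 available); size ties keep the component with the smallest row-major
origin. Both choices are conventions, not identities; they are configurable
because "largest connected region" does not pin them down.

## Tiling

The tile grid is anchored at the tumor-mask bounding-box origin and only
full tiles inside the box are considered. The tissue fraction of a tile is
the fraction of its pixels inside the *tumor* mask (not the Otsu tissue
mask), and the retention rule is strict: fraction > 0.75. The 2.5x stage
crops the bounding box of the whole region and carries an explicit
in-region pixel mask; features at 2.5x are computed only over in-region
pixels rather than over a rectangle padded with background, which would
contaminate the texture statistics. At 40x the tile list is capped at 200
by a seeded uniform sample without replacement that preserves row-major
order; sampling is a projection (resampling a sampled list is the
identity).

Color normalization is Reinhard mean/sd transfer in CIELAB: center, rescale
per channel to the reference sd, shift to the reference mean, convert back
and clip. A zero-variance channel passes through as a pure shift. The
reference statistics default to mid-gray stained-tissue values and are
configurable; stain-deconvolution methods are deliberately not used because
the synthetic slides are not dye mixtures.

## Texture features

Gray levels: 16 equal-width bins over the fixed range [0, 255]
(`level = floor(v*16/256)+1`), not per-tile min–max. The fixed range keeps
low/high-gray-level-emphasis features comparable across tiles and slides;
`n_gray` is configurable.

Per scale the catalog is 17 first-order + 7 GLCM + 11 GLRLM x 4 angles = 68
features; three scales give 204. Canonical ids are `<Name>_<scale>` for
first-order, `glcm_<name>_0_<scale>` and `glrlm_<NAME>_<angle>_<scale>`
otherwise (e.g. `glrlm_SRLGLE_90_2.5`, `Kurtosis_10`).

Definitions worth pinning down:

* Variance is the population variance; Skewness/Kurtosis are standardized
  third/fourth moments with Kurtosis in Pearson (non-excess) form — a
  normal sample scores ≈ 3. Zero-variance tiles return 0 for both (guard).
* Entropy and Uniformity are computed over the 16-bin quantized histogram,
  entropy in bits. Percentiles interpolate linearly between order
  statistics.
* GLCM: distance 1, angle 0 only, ordered pairs with both pixels valid,
  symmetrized by adding the transpose, normalized to sum 1. The correlation
  guard returns 0 when the marginal is degenerate.
* GLRLM: runs are maximal same-level segments along the angle direction
  with offsets 0°→(0,+1), 45°→(−1,+1), 90°→(−1,0), 135°→(−1,−1); invalid
  pixels break runs and are not counted, so `Σ_ij j·p(i,j)` equals the
  valid-pixel count at every angle.

Per-slide aggregation is the unweighted mean of tile features within each
scale (median available); the 2.5x value is the single region value. The
vectorized engines are verified against naive pair/run enumeration oracles
to 1e-12 on random masked tiles.

## Signature

Z-score parameters (mean, sd with ddof = 1) are estimated on the discovery
table only and reapplied, never refitted, to validation cohorts;
zero-variance features are flagged unusable and excluded.

Selection maximizes the L1-penalized Cox partial likelihood over a
log-spaced 50-point penalty path (`scikit-survival` coordinate descent).
The penalty is chosen by 10-fold cross-validated partial-likelihood
deviance in the Verweij–van Houwelingen form
`-2·[logPL_all(β_−k) − logPL_train(β_−k)]`, with Breslow ties in the
evaluator (the synthetic event times are continuous, so ties have measure
zero). Folds are event-stratified and seeded so every fold is estimable.
The minimizing penalty is the default; the one-standard-error rule is a
config option. The score is the weighted linear combination of the selected
z-scored features; the discovery-set median (midpoint of central order
statistics for even n) is the cutoff, with scores strictly above it labeled
high-risk and ties going to low-risk.

## Survival statistics

Cox models use Efron tie handling and Wald CIs `exp(β ± 1.96·se)`;
AIC = −2·logPL + 2k. Categorical covariates are reference-coded with fixed
clinical references (age < 65, male, never-smoker, upper/middle lobe,
surgery alone, G1/G2, TNM I, low risk), so hazard ratios read
"comparison vs reference". The univariable screen keeps factors with any
level's Wald P < 0.05; the multivariable model then runs backward AIC
elimination from that set (drop the covariate whose removal lowers AIC
most; AIC ties drop the later-listed covariate; stop when no removal
helps). The likelihood-ratio test compares nested fits on identical
records with df equal to the parameter-count difference.

Harrell's C counts a pair usable when the shorter observed time carries an
event; tied scores score 1/2. Its CI is a seeded percentile bootstrap over
patients (2000 resamples by default; resamples without admissible pairs are
skipped). The time-dependent AUC is the IPCW cumulative-cases /
dynamic-controls estimator with censoring weights from the Kaplan–Meier
estimate of the censoring distribution, evaluated on a 12–60-month grid
and at the 60-month horizon; with no censoring it reduces exactly to the
plain ROC AUC of event-by-t versus event-after-t.

## Histo-genomics

The zero-expression filter removes genes that are zero in **all** samples
(the most conservative reading; `any` and `fraction:<f>` variants are
config options). Differential expression is the two-sided Wilcoxon
rank-sum test per gene — exact null distribution when both groups have
fewer than 10 samples, tie-corrected normal approximation otherwise — with
Benjamini–Hochberg step-up adjustment across genes and significance at
adjusted P < 0.05. Over-representation is the one-sided hypergeometric
tail P(overlap ≥ observed) with sets intersected against the tested
universe, BH-adjusted across sets.

ssGSEA follows the standard single-sample definition: per sample, genes
are ranked descending (ties share average rank) and the score is the sum
over the ranked list of the difference between the rank^α-weighted in-set
ECDF and the unweighted out-of-set ECDF, with α = 0.25. Scores depend on
expression only through ranks, so any strictly increasing per-sample
transform leaves them unchanged. Pathway–feature association dichotomizes
samples at each feature's median (strictly above vs rest) and rank-sum
tests the pathway scores between halves; matrix-wide BH is off by default
because the association table is exploratory.

## Synthetic data: what it emulates, what it does not

Slides are painted in three layers — white (255) scanner background,
textured tissue, textured tumor region (disc/ellipse/rectangle/polygon) —
with pixel-exact ground-truth masks. Textures control only second-order
statistics (stripes, checkerboards, quantile-thresholded Gaussian blobs,
smoothed random fields, plus i.i.d. gray noise); they do not imitate H&E
stain chemistry, nuclear morphology or scanner artifacts. Consequently the
segmentation and feature tests demonstrate geometric and statistical
correctness of the pipeline, not clinical performance on real slides.

Survival cohorts use exponential event times with rate
`h0·exp(Σβ_k z_k + stage_effect·stage_level)` and exponential censoring
truncated at the follow-up horizon — the memoryless choice keeps every
calibration check closed-form. Defaults: `h0 = 1/60` per month,
censoring rate `1/180`, 120-month follow-up, giving ≈ 30 % censoring under
a null signal (≈ 35–40 % with a strong planted signal, because the
low-risk half survives into censoring territory). `stage_effect` defaults
to 0 so feature-recovery experiments have no omitted covariate; the
model-comparison experiment sets it to 0.7 per stage level (hazard ratio
≈ 2 per step, the magnitude typical of resectable-LUAD staging).

Expression matrices are genes × samples i.i.d. N(5, 1) with `n_de` planted
genes shifted by a fixed amount in the high-risk group; one "positive" set
draws 80 % of its members from the planted genes, the rest are uniform
draws. Clinical covariates are drawn from marginals typical of a surgical
lung-adenocarcinoma cohort and are independent of outcome unless
`stage_effect` is set.

## Benchmark problem sizes

The acceptance script and the acceptance tests run: oracle equivalence on
200 random masked tiles ≤ 8×8; signature recovery on 20 cohorts of n = 500
with 3 planted features among 204 (10-fold CV); log-rank size on 500 null
cohorts of n = 100; hazard-ratio recovery at n = 2000; model comparison on
20 cohorts of n = 300; histo-genomic power on 20 replicates of 1000 genes
× 100 samples and the null control on 20 replicates of 500 genes × 60
samples. These sizes make every stochastic rate estimable while keeping a
full run around half a minute on one CPU.

## Known limitations

* The default patch scorer is intensity-based; tumors not separable by
  darkness need a user-supplied classifier.
* GLCM is horizontal-only by construction of the catalog; anisotropy is
  captured only through the four GLRLM angles.
* The tissue mask assumes a white background; slides without background
  exercise the degenerate Otsu path and mask everything as tissue.
* No competing risks, time-varying covariates or frailty terms; no GO DAG
  traversal (gene sets are user-supplied GMT).
* Proprietary whole-slide formats are out of scope; inputs are PNG/TIFF
  rasters.
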