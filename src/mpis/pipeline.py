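"""End-to-end pipeline driver: slides -> features -> signature -> statistics.

Runs the six stages in order (segmentation, tiling, features, signature,
survival, histo-genomics), writing every artifact under one output
directory, with a JSON run log recording the configuration hash, per-stage
timings and the artifacts produced. Identical configuration and inputs give
byte-identical tabular outputs.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from . import features as mfeat
from . import histogenomics as mhg
from . import segmentation as mseg
from . import signature as msig
from . import survival as msurv
from . import tiling as mtile

__all__ = ["PipelineConfig", "run_pipeline", "compute_slide_features"]


@dataclass
class PipelineConfig:
    """All pipeline constants and paths; defaults follow the method's design.

    The geometry block (window 224, tile 1024, 75% tissue rule, 200-tile cap
    at 40x, gray levels 16, tenfold CV, alpha 0.05, 60-month horizon) holds
    the method's standard constants; smaller values are legitimate for
    reduced-scale runs as long as ``window`` stays divisible by the largest
    downsample factor.
    """

    slides_dir: str = ""
    clinical_csv: str = ""
    expression_tsv: str = ""
    gmt: str = ""
    out_dir: str = "mpis_out"
    # geometry
    window: int = 224
    tile_size: int = 1024
    tissue_fraction_min: float = 0.75
    sample_cap: int = 200
    n_gray: int = 16
    scales: tuple[float, ...] = (2.5, 10, 40)
    # modeling
    cv_folds: int = 10
    alpha: float = 0.05
    horizon_months: float = 60.0
    covariates: tuple[str, ...] = ("age_group", "sex", "smoking", "site",
                                   "treatment", "differentiation", "tnm_stage",
                                   "risk_group")
    fixed_lambda: float | None = None
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.tissue_fraction_min < 1.0):
            raise ValueError("tissue_fraction_min must be in [0, 1)")
        if self.sample_cap < 1 or self.cv_folds < 2 or self.n_gray < 2:
            raise ValueError("sample_cap, cv_folds and n_gray out of range")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        biggest = max(mtile.DOWNSAMPLE[s] for s in self.scales)
        if self.window % biggest:
            raise ValueError("window must be divisible by the largest downsample")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")   # output location does not change the analysis
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def compute_slide_features(slide: np.ndarray, config: PipelineConfig,
                           seed: int, slide_id: str = "slide",
                           ) -> tuple[mfeat.FeatureVector, mseg.SegmentationResult]:
    """Segmentation, tiling and the 204-feature vector for one slide."""
    seg = mseg.segment_slide(slide, window=config.window)
    if not seg.tumor_cells.any():
        return mfeat.FeatureVector(slide_id=slide_id), seg
    pyramid = mtile.SlidePyramid(base=slide)
    tiles_by_scale: dict[float, list] = {}
    for scale in config.scales:
        if scale == 2.5:
            t = mtile.extract_region_2p5x(pyramid, seg.tumor_cells,
                                          window=config.window)
            tiles_by_scale[scale] = [(t.image, t.mask)]
        else:
            tiles = mtile.enumerate_tiles(
                pyramid, seg.tumor_cells, scale,
                tissue_fraction_min=config.tissue_fraction_min,
                tile_size=config.tile_size, window=config.window)
            if scale == 40:
                tiles = mtile.sample_tiles(tiles, cap=config.sample_cap,
                                           seed=seed)
            tiles_by_scale[scale] = [(t.image, None) for t in tiles]
    vec = mfeat.slide_feature_vector(slide_id, tiles_by_scale,
                                     n_gray=config.n_gray)
    return vec, seg


def _stamp(path: Path, config_hash: str, seed: int) -> None:
    text = path.read_text()
    path.write_text(f"# mpis config_hash={config_hash} seed={seed}\n" + text)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run log (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    log: dict = {"config_hash": chash, "seed": config.seed, "stages": []}
    artifacts: list[str] = []

    def stage(name):
        def deco(fn):
            t0 = _time.perf_counter()
            try:
                fn()
            except Exception as exc:
                log["stages"].append({"name": name, "status": "error",
                                      "error": str(exc)})
                _write_log(out, log)
                raise RuntimeError(f"pipeline halted at stage {name!r}: {exc}") \
                    from exc
            log["stages"].append({
                "name": name, "status": "ok",
                "seconds": round(_time.perf_counter() - t0, 3)})
        return deco

    state: dict = {}

    @stage("segmentation")
    def _seg():
        slide_paths = sorted(Path(config.slides_dir).glob("*.png")) \
            if config.slides_dir else []
        if not slide_paths:
            raise FileNotFoundError(f"no slide PNGs in {config.slides_dir!r}")
        state["slides"] = {p.stem: mio.read_image_png(p) for p in slide_paths}

    @stage("tiling_features")
    def _feat():
        rows = []
        for i, (sid, img) in enumerate(sorted(state["slides"].items())):
            vec, seg = compute_slide_features(
                img, config, seed=config.seed + i, slide_id=sid)
            mio.write_mask_png(seg.tumor_cells, out / f"tumor_cells_{sid}.png")
            artifacts.append(f"tumor_cells_{sid}.png")
            if vec.values:
                rows.append(vec.to_series())
            else:
                warnings.warn(f"slide {sid}: no tumor region, skipped")
        table = pd.DataFrame(rows)
        table.index.name = "slide_id"
        complete = table.dropna(axis=0)
        if len(complete) < len(table):
            warnings.warn(f"{len(table) - len(complete)} slides with "
                          "incomplete feature vectors dropped")
        state["features"] = complete
        mio.write_feature_table(complete, out / "features.csv")
        _stamp(out / "features.csv", chash, config.seed)
        artifacts.append("features.csv")

    @stage("signature")
    def _sig():
        clinical = mio.read_clinical(config.clinical_csv)
        feats = state["features"]
        clinical = clinical[clinical["slide_id"].isin(feats.index)]
        state["clinical"] = clinical
        model = msig.TextureSignatureModel(feats, clinical)
        res = model.fit(folds=config.cv_folds, seed=config.seed,
                        fixed_lambda=config.fixed_lambda)
        state["signature"] = res
        res.to_json(out / "model.json")
        mio.write_scores(res.scores, out / "scores.csv")
        _stamp(out / "scores.csv", chash, config.seed)
        artifacts.extend(["model.json", "scores.csv"])

    @stage("stratification")
    def _strat():
        res = state["signature"]
        clinical = state["clinical"].copy()
        groups = res.risk_groups.reindex(clinical["slide_id"])
        clinical["risk_group"] = groups.to_numpy()
        state["clinical"] = clinical
        km = msurv.km_estimate(clinical, "risk_group")
        km_table = pd.concat([t.assign(group=g) for g, t in km.items()])
        km_table.to_csv(out / "km_curves.csv", index=False)
        _stamp(out / "km_curves.csv", chash, config.seed)
        artifacts.append("km_curves.csv")

    @stage("survival")
    def _surv():
        clinical = state["clinical"]
        if clinical["risk_group"].nunique() == 2:
            chi2, p = msurv.logrank_test(clinical)
        else:
            chi2, p = float("nan"), float("nan")
            warnings.warn("single risk group: log-rank skipped")
        rows = []
        kept = msurv.univariable_screen(clinical, list(config.covariates),
                                        alpha=config.alpha)
        for cov in config.covariates:
            try:
                f = msurv.cox_fit(clinical, [cov])
            except (RuntimeError, ValueError):
                continue
            for term, r in f.summary.iterrows():
                rows.append({"analysis": "univariable", "term": term,
                             "hr": r["hr"], "ci_low": r["hr_ci_low"],
                             "ci_high": r["hr_ci_high"], "p": r["p"]})
        final = msurv.stepwise_aic(clinical, kept) if kept else None
        if final is not None:
            for term, r in final.summary.iterrows():
                rows.append({"analysis": "multivariable", "term": term,
                             "hr": r["hr"], "ci_low": r["hr_ci_low"],
                             "ci_high": r["hr_ci_high"], "p": r["p"]})
        pd.DataFrame(rows).to_csv(out / "cox_tables.csv", index=False)
        _stamp(out / "cox_tables.csv", chash, config.seed)
        artifacts.append("cox_tables.csv")

        comparison_rows = [{"model": "logrank", "c_index": float("nan"),
                            "ci_low": float("nan"), "ci_high": float("nan"),
                            "aic": float("nan"), "statistic": chi2, "p": p}]
        clin_covs = [c for c in ("tnm_stage", "differentiation")
                     if clinical[c].nunique() > 1]
        try:
            clinical_fit = msurv.cox_fit(clinical, clin_covs)
            full_fit = msurv.cox_fit(clinical, clin_covs + ["risk_group"])
            lrt_stat, lrt_p = msurv.likelihood_ratio_test(full_fit, clinical_fit)
            for name, f in (("clinical", clinical_fit), ("full", full_fit)):
                scores = f.predict_partial_hazard_order(clinical)
                cval, (lo, hi) = msurv.c_index(clinical, scores,
                                               n_boot=200, seed=config.seed)
                comparison_rows.append({
                    "model": name, "c_index": cval, "ci_low": lo,
                    "ci_high": hi, "aic": f.aic,
                    "statistic": lrt_stat if name == "full" else float("nan"),
                    "p": lrt_p if name == "full" else float("nan")})
            auc, auc_table = msurv.time_dependent_auc(
                clinical,
                full_fit.predict_partial_hazard_order(clinical),
                horizon=config.horizon_months)
            auc_table.to_csv(out / "auc_grid.csv", index=False)
            _stamp(out / "auc_grid.csv", chash, config.seed)
            artifacts.append("auc_grid.csv")
        except (RuntimeError, ValueError) as exc:
            warnings.warn(f"model comparison skipped: {exc}")
        pd.DataFrame(comparison_rows).to_csv(out / "model_comparison.csv",
                                             index=False)
        _stamp(out / "model_comparison.csv", chash, config.seed)
        artifacts.append("model_comparison.csv")

    @stage("histogenomics")
    def _hg():
        if not config.expression_tsv:
            state["hg_skipped"] = True
            return
        expr = mio.read_expression(config.expression_tsv)
        sets = mhg.read_gmt(config.gmt) if config.gmt else []
        clinical = state["clinical"]
        groups = pd.Series(clinical["risk_group"].to_numpy(),
                           index=clinical["slide_id"])
        expr = mhg.filter_zero_genes(expr)
        common = [s for s in expr.columns if s in groups.index]
        expr = expr[common]
        deg = mhg.deg_wilcoxon(expr, groups.loc[common], alpha=config.alpha)
        deg.to_csv(out / "deg_table.csv")
        artifacts.append("deg_table.csv")
        if sets:
            ora = mhg.overrepresentation_test(
                list(deg.index[deg["significant"]]), list(expr.index), sets,
                alpha=config.alpha)
            ora.to_csv(out / "ora_table.csv")
            ss = mhg.ssgsea_scores(expr, sets)
            ss.to_csv(out / "ssgsea_scores.csv")
            res = state["signature"]
            feats = state["features"].loc[
                [s for s in common if s in state["features"].index],
                res.selected_features] if res.selected_features else None
            if feats is not None and len(feats):
                assoc = mhg.pathway_feature_association(ss[feats.index], feats)
                assoc.to_csv(out / "pathway_feature_association.csv")
                artifacts.append("pathway_feature_association.csv")
            artifacts.extend(["ora_table.csv", "ssgsea_scores.csv"])

    if state.get("hg_skipped"):
        log["stages"][-1]["status"] = "skipped"
    log["artifacts"] = artifacts
    _write_log(out, log)
    return log


def _write_log(out: Path, log: dict) -> None:
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
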