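"""Texture-signature construction and risk stratification.

The signature is a sparse weighted linear combination of Z-scored texture
features selected by an L1-penalized Cox partial likelihood (LASSO-Cox) with
k-fold cross-validation on the discovery cohort. Each patient's score is

    MPIS = sum_k beta_k * z_k

over the selected features, and the discovery-set median score is the fixed
cutoff stratifying every cohort into high-risk (score strictly greater than
the cutoff) and low-risk groups; validation cohorts reuse the discovery
Z-score parameters and cutoff unchanged.

The module exposes both the operation-level functions (``zscore_fit``,
``lasso_cox_select``, ``mpis_score``, ``set_cutoff_and_stratify``) and a
model/results pair (:class:`TextureSignatureModel` /
:class:`TextureSignatureResults`) that packages the fitted signature with
its diagnostics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "ZScoreParams",
    "zscore_fit",
    "zscore_apply",
    "cox_partial_loglik",
    "lasso_cox_select",
    "mpis_score",
    "set_cutoff_and_stratify",
    "TextureSignatureModel",
    "TextureSignatureResults",
]


# ---------------------------------------------------------------------------
# Z-score normalization
# ---------------------------------------------------------------------------

@dataclass
class ZScoreParams:
    """Per-feature mean/sd fitted on the discovery table.

    Zero-variance features are flagged unusable and excluded from modeling
    (their z-scores are undefined).
    """

    mean: pd.Series
    sd: pd.Series
    usable: list[str] = field(default_factory=list)


def zscore_fit(table: pd.DataFrame, ddof: int = 1) -> ZScoreParams:
    """Estimate Z-score parameters on a reference (discovery) feature table."""
    if len(table) < 2:
        raise ValueError("zscore_fit needs >= 2 rows")
    mean = table.mean()
    sd = table.std(ddof=ddof)
    usable = [c for c in table.columns if sd[c] > 0 and np.isfinite(sd[c])]
    return ZScoreParams(mean=mean, sd=sd, usable=usable)


def zscore_apply(table: pd.DataFrame, params: ZScoreParams) -> pd.DataFrame:
    """Apply previously fitted Z-score parameters (validation is never refit)."""
    unseen = [c for c in table.columns if c not in params.mean.index]
    if unseen:
        raise ValueError(f"features without fitted parameters: {unseen}")
    cols = [c for c in table.columns if c in params.usable]
    return (table[cols] - params.mean[cols]) / params.sd[cols]


# ---------------------------------------------------------------------------
# Cox partial likelihood and cross-validated LASSO selection
# ---------------------------------------------------------------------------

def cox_partial_loglik(eta: np.ndarray, time: np.ndarray,
                       event: np.ndarray) -> float:
    """Breslow-ties Cox partial log-likelihood at a fixed linear predictor."""
    idx = np.argsort(time, kind="stable")
    t, e, et = time[idx], np.asarray(event, bool)[idx], np.asarray(eta, float)[idx]
    log_risk = np.logaddexp.accumulate(et[::-1])[::-1]
    first = np.searchsorted(t, t, side="left")  # ties share one risk set
    return float(np.sum(et[e] - log_risk[first][e]))


def _event_stratified_folds(event: np.ndarray, folds: int,
                            seed: int) -> np.ndarray:
    """Round-robin fold labels, shuffled within event and censored strata."""
    rng = np.random.default_rng(seed)
    assign = np.empty(len(event), dtype=int)
    for value in (0, 1):
        idx = np.nonzero(event == value)[0]
        rng.shuffle(idx)
        assign[idx] = np.arange(len(idx)) % folds
    return assign


def lasso_cox_select(ztable: pd.DataFrame, survival: pd.DataFrame,
                     folds: int = 10, seed: int = 0,
                     lambda_rule: str = "min",
                     fixed_lambda: float | None = None,
                     n_alphas: int = 50, alpha_min_ratio: float = 0.01,
                     ) -> tuple[pd.Series, float, pd.DataFrame]:
    """LASSO-Cox feature selection with k-fold cross-validated deviance.

    ``ztable`` is the Z-scored feature table (rows aligned with ``survival``
    by slide_id); ``survival`` needs ``time_months`` and ``event`` columns.
    The penalty is chosen on a log-spaced path to minimize the mean
    cross-validated partial-likelihood deviance (Verweij-van Houwelingen:
    ``-2 * [logPL_all(beta_-k) - logPL_train(beta_-k)]`` summed over held-out
    folds), with event-stratified seeded fold assignment. ``lambda_rule``
    'min' picks the minimizing penalty, '1se' the largest penalty within one
    standard error of the minimum. ``fixed_lambda`` bypasses cross-validation.

    Returns ``(nonzero coefficients, chosen lambda, cv path table)``.
    """
    survival = survival.set_index("slide_id") if "slide_id" in survival else survival
    common = [i for i in ztable.index if i in survival.index]
    if len(common) != len(ztable):
        raise ValueError("feature and survival tables are not aligned by slide_id")
    time = survival.loc[ztable.index, "time_months"].to_numpy(dtype=float)
    event = survival.loc[ztable.index, "event"].to_numpy(dtype=int)
    if event.sum() == 0:
        raise ValueError("no events in the cohort")
    X = ztable.to_numpy(dtype=float)
    y = Surv.from_arrays(event.astype(bool), time)

    if fixed_lambda is not None:
        model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=[fixed_lambda],
                                       tol=1e-9, max_iter=10 ** 6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(X, y)
        coefs = pd.Series(model.coef_[:, 0], index=ztable.columns)
        nz = coefs[coefs != 0]
        if nz.empty:
            warnings.warn("all coefficients zero at the fixed penalty: "
                          "empty model")
        return nz, float(fixed_lambda), pd.DataFrame()

    if event.sum() < folds:
        raise ValueError(f"need >= {folds} events for {folds}-fold CV")

    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas,
                                  alpha_min_ratio=alpha_min_ratio)
    path.fit(X, y)
    alphas = np.asarray(path.alphas_)

    fold_of = _event_stratified_folds(event, folds, seed)
    dev = np.zeros((folds, len(alphas)))
    for k in range(folds):
        tr = fold_of != k
        mk = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(alphas))
        mk.fit(X[tr], Surv.from_arrays(event[tr].astype(bool), time[tr]))
        n_fit = mk.coef_.shape[1]   # the path may stop early on a fold
        for a in range(len(alphas)):
            beta = mk.coef_[:, min(a, n_fit - 1)]
            ll_all = cox_partial_loglik(X @ beta, time, event)
            ll_tr = cox_partial_loglik(X[tr] @ beta, time[tr], event[tr])
            dev[k, a] = -2.0 * (ll_all - ll_tr)
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(folds)
    best = int(np.argmin(mean_dev))
    if lambda_rule == "min":
        chosen = best
    elif lambda_rule == "1se":
        ok = mean_dev <= mean_dev[best] + se_dev[best]
        chosen = int(np.nonzero(ok)[0][0])   # alphas are decreasing
    else:
        raise ValueError("lambda_rule must be 'min' or '1se'")

    cv_path = pd.DataFrame({"lambda": alphas, "mean_deviance": mean_dev,
                            "se_deviance": se_dev})
    coefs = pd.Series(path.coef_[:, chosen], index=ztable.columns)
    nz = coefs[coefs != 0]
    if nz.empty:
        warnings.warn("all coefficients zero at the chosen penalty: empty model")
    return nz, float(alphas[chosen]), cv_path


def mpis_score(ztable: pd.DataFrame | pd.Series,
               coefficients: pd.Series) -> pd.Series | float:
    """Weighted linear combination ``sum_k beta_k * z_k`` of selected features."""
    if isinstance(ztable, pd.Series):
        missing = [f for f in coefficients.index if f not in ztable.index]
        if missing:
            raise ValueError(f"row is missing selected features: {missing}")
        return float((ztable[coefficients.index] * coefficients).sum())
    missing = [f for f in coefficients.index if f not in ztable.columns]
    if missing:
        raise ValueError(f"table is missing selected features: {missing}")
    return ztable[list(coefficients.index)] @ coefficients


def set_cutoff_and_stratify(scores_by_cohort: dict[str, pd.Series],
                            discovery: str,
                            ) -> tuple[float, dict[str, pd.Series]]:
    """Median-cutoff risk stratification, discovery cutoff applied everywhere.

    The cutoff is the median discovery-set score (midpoint of the two
    central order statistics for even n); a patient is high-risk iff the
    score is strictly greater than the cutoff, so a score exactly at the
    cutoff is low-risk.
    """
    if discovery not in scores_by_cohort or len(scores_by_cohort[discovery]) == 0:
        raise ValueError("discovery cohort is empty or absent")
    cutoff = float(np.median(scores_by_cohort[discovery].to_numpy()))
    labels = {
        cohort: pd.Series(np.where(s.to_numpy() > cutoff, "high", "low"),
                          index=s.index, name="risk_group")
        for cohort, s in scores_by_cohort.items()
    }
    return cutoff, labels


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class TextureSignatureModel:
    """Prognostic texture-signature model for one discovery cohort.

    Parameters
    ----------
    features : DataFrame
        Per-slide feature table, indexed by slide_id (one column per
        canonical feature id).
    survival : DataFrame
        Clinical table with ``slide_id``, ``time_months`` and ``event``
        columns (extra covariate columns are ignored here).
    """

    def __init__(self, features: pd.DataFrame, survival: pd.DataFrame):
        surv = survival.set_index("slide_id") if "slide_id" in survival else survival
        missing = [i for i in features.index if i not in surv.index]
        if missing:
            raise ValueError(f"slides without survival records: {missing[:5]}")
        self.features = features
        self.survival = surv.loc[features.index]

    @classmethod
    def from_dataframes(cls, features: pd.DataFrame,
                        survival: pd.DataFrame) -> "TextureSignatureModel":
        return cls(features, survival)

    def fit(self, folds: int = 10, seed: int = 0, lambda_rule: str = "min",
            fixed_lambda: float | None = None) -> "TextureSignatureResults":
        zparams = zscore_fit(self.features)
        ztable = zscore_apply(self.features, zparams)
        coefs, lam, cv_path = lasso_cox_select(
            ztable, self.survival, folds=folds, seed=seed,
            lambda_rule=lambda_rule, fixed_lambda=fixed_lambda)
        scores = mpis_score(ztable, coefs) if not coefs.empty else \
            pd.Series(0.0, index=ztable.index)
        cutoff, labels = set_cutoff_and_stratify({"discovery": scores},
                                                 "discovery")
        return TextureSignatureResults(
            model=self, params=coefs, zscore_params=zparams, lambda_=lam,
            cv_path=cv_path, cutoff=cutoff, scores=scores,
            risk_groups=labels["discovery"], folds=folds, seed=seed)


@dataclass
class TextureSignatureResults:
    """Fitted signature: coefficients, normalization, cutoff, diagnostics."""

    model: TextureSignatureModel | None
    params: pd.Series              # nonzero beta_k, indexed by feature id
    zscore_params: ZScoreParams
    lambda_: float
    cv_path: pd.DataFrame
    cutoff: float
    scores: pd.Series              # discovery scores
    risk_groups: pd.Series         # discovery labels
    folds: int = 10
    seed: int = 0

    @property
    def selected_features(self) -> list[str]:
        return list(self.params.index)

    def score(self, features: pd.DataFrame) -> pd.Series:
        """Signature scores for any cohort, using the fitted normalization."""
        z = zscore_apply(features, self.zscore_params)
        return mpis_score(z, self.params)

    def stratify(self, features: pd.DataFrame | None = None,
                 scores: pd.Series | None = None) -> pd.Series:
        """Risk labels using the frozen discovery cutoff (high iff > cutoff)."""
        if scores is None:
            if features is None:
                raise ValueError("provide features or scores")
            scores = self.score(features)
        return pd.Series(np.where(scores.to_numpy() > self.cutoff, "high", "low"),
                         index=scores.index, name="risk_group")

    def summary(self) -> str:
        lines = [
            "Texture signature (LASSO-Cox)",
            "=" * 46,
            f"features selected : {len(self.params)} / "
            f"{len(self.zscore_params.usable)} usable",
            f"penalty lambda    : {self.lambda_:.6g}",
            f"cv folds / seed   : {self.folds} / {self.seed}",
            f"median cutoff     : {self.cutoff:.4g}",
            f"high-risk fraction: "
            f"{(self.risk_groups == 'high').mean():.3f}",
            "-" * 46,
            f"{'feature':<32}{'coef':>12}",
        ]
        for fid, beta in self.params.items():
            lines.append(f"{fid:<32}{beta:>12.5f}")
        return "\n".join(lines)

    def plot_km(self, records: pd.DataFrame, ax=None):
        """Kaplan-Meier curves of the high/low-risk groups (matplotlib axes).

        ``records`` needs ``slide_id``, ``time_months`` and ``event``; risk
        groups come from the fitted cutoff via the discovery labels or, for
        unseen slides, must be joined by the caller.
        """
        import matplotlib.pyplot as plt
        from lifelines import KaplanMeierFitter

        if ax is None:
            _, ax = plt.subplots()
        rec = records.set_index("slide_id") if "slide_id" in records \
            else records
        groups = self.risk_groups.reindex(rec.index)
        for label in ("low", "high"):
            sub = rec[groups == label]
            if len(sub) == 0:
                continue
            kmf = KaplanMeierFitter()
            kmf.fit(sub["time_months"], sub["event"],
                    label=f"{label}-risk (n={len(sub)})")
            kmf.plot_survival_function(ax=ax)
        ax.set_xlabel("months since surgery")
        ax.set_ylabel("overall survival probability")
        return ax

    # -- persistence --------------------------------------------------------

    def to_json(self, path=None) -> str:
        payload = {
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "zscore_mean": {k: float(v) for k, v in
                            self.zscore_params.mean.items()},
            "zscore_sd": {k: float(v) for k, v in self.zscore_params.sd.items()},
            "usable": self.zscore_params.usable,
            "cutoff": self.cutoff,
            "lambda": self.lambda_,
            "folds": self.folds,
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TextureSignatureResults":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        zp = ZScoreParams(mean=pd.Series(payload["zscore_mean"]),
                          sd=pd.Series(payload["zscore_sd"]),
                          usable=list(payload["usable"]))
        return cls(model=None, params=pd.Series(payload["coefficients"]),
                   zscore_params=zp, lambda_=float(payload["lambda"]),
                   cv_path=pd.DataFrame(), cutoff=float(payload["cutoff"]),
                   scores=pd.Series(dtype=float),
                   risk_groups=pd.Series(dtype=object),
                   folds=int(payload["folds"]), seed=int(payload["seed"]))
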