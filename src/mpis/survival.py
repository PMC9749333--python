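"""Survival machinery: Kaplan-Meier, log-rank, Cox models, C-index, AUC(t).

Covers the model-evaluation stage of the pipeline: product-limit curves and
log-rank comparison of risk groups, univariable Cox screening at P < 0.05,
backward AIC-stepwise multivariable Cox, likelihood-ratio comparison of
nested models, Harrell's concordance with a bootstrap CI, and IPCW
cumulative/dynamic time-dependent AUC at a 5-year horizon.

Categorical covariates are reference-coded with fixed clinical reference
levels (age < 65, male, never-smoker, upper/middle lobe, surgery alone,
well-moderately differentiated, TNM stage I, low risk); hazard ratios are
therefore "comparison vs. reference". Cox fits use Efron tie handling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import concordance_index as _ll_concordance

__all__ = [
    "REFERENCE_LEVELS",
    "encode_covariates",
    "km_estimate",
    "logrank_test",
    "CoxFit",
    "cox_fit",
    "univariable_screen",
    "stepwise_aic",
    "likelihood_ratio_test",
    "c_index",
    "time_dependent_auc",
]

REFERENCE_LEVELS = {
    "age_group": "<65",
    "sex": "Male",
    "smoking": "Never",
    "site": "Upper/Middle",
    "treatment": "Surg.",
    "differentiation": "G1/G2",
    "tnm_stage": "I",
    "risk_group": "low",
}


def encode_covariates(records: pd.DataFrame, covariates: list[str],
                      ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Reference-code covariates into a numeric design matrix.

    Numeric columns pass through unchanged; categorical columns become
    0/1 indicators for every non-reference level (reference from
    :data:`REFERENCE_LEVELS`, else the lexicographically first level).
    Returns the design matrix and the covariate -> encoded-columns map.
    """
    design = {}
    groups: dict[str, list[str]] = {}
    for cov in covariates:
        col = records[cov]
        if pd.api.types.is_numeric_dtype(col):
            design[cov] = col.astype(float)
            groups[cov] = [cov]
            continue
        levels = sorted(col.astype(str).unique())
        ref = REFERENCE_LEVELS.get(cov, levels[0])
        if ref not in levels:
            ref = levels[0]
        groups[cov] = []
        for lvl in levels:
            if lvl == ref:
                continue
            name = f"{cov}[{lvl}]"
            design[name] = (col.astype(str) == lvl).astype(float)
            groups[cov].append(name)
    return pd.DataFrame(design, index=records.index), groups


def km_estimate(records: pd.DataFrame, group_col: str | None = None,
                ) -> dict[str, pd.DataFrame]:
    """Kaplan-Meier product-limit curves, one table per group.

    Each table has columns ``time, at_risk, deaths, censored, survival``;
    censored subjects leave the risk set after their recorded time.
    """
    out: dict[str, pd.DataFrame] = {}
    if group_col is None:
        parts = {"all": records}
    else:
        parts = {str(g): sub for g, sub in records.groupby(group_col)}
    for name, sub in parts.items():
        if len(sub) == 0:
            raise ValueError(f"group {name!r} is empty")
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_months"], sub["event"])
        et = kmf.event_table
        surv = kmf.survival_function_["KM_estimate"]
        out[name] = pd.DataFrame({
            "time": et.index.to_numpy(dtype=float),
            "at_risk": et["at_risk"].to_numpy(dtype=int),
            "deaths": et["observed"].to_numpy(dtype=int),
            "censored": et["censored"].to_numpy(dtype=int),
            "survival": surv.reindex(et.index).to_numpy(dtype=float),
        }).reset_index(drop=True)
    return out


def logrank_test(records: pd.DataFrame, group_col: str = "risk_group",
                 ) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    groups = records[group_col].unique()
    if len(groups) != 2:
        raise ValueError(f"log-rank needs exactly two groups, got {list(groups)}")
    if records["event"].sum() == 0:
        raise ValueError("no events: log-rank statistic undefined")
    a = records[records[group_col] == groups[0]]
    b = records[records[group_col] == groups[1]]
    res = _ll_logrank(a["time_months"], b["time_months"],
                      a["event"], b["event"])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model with its diagnostics."""

    covariates: list[str]
    summary: pd.DataFrame          # coef, se, HR, CI bounds, p per column
    log_likelihood: float
    n_params: int
    aic: float
    n: int
    n_events: int
    concordance: float
    design_columns: list[str] = field(default_factory=list)
    _fitter: CoxPHFitter | None = field(default=None, repr=False)

    def summary_text(self) -> str:
        lines = [f"Cox PH fit: n={self.n}, events={self.n_events}, "
                 f"logL={self.log_likelihood:.3f}, AIC={self.aic:.3f}, "
                 f"C-index={self.concordance:.3f}",
                 f"{'term':<28}{'HR':>8}{'95% CI':>20}{'P':>10}"]
        for term, row in self.summary.iterrows():
            ci = f"({row['hr_ci_low']:.2f}-{row['hr_ci_high']:.2f})"
            lines.append(f"{term:<28}{row['hr']:>8.2f}{ci:>20}"
                         f"{row['p']:>10.4f}")
        return "\n".join(lines)

    def predict_partial_hazard_order(self, records: pd.DataFrame) -> pd.Series:
        """Linear predictor (risk score) for new records."""
        design, _ = encode_covariates(records, self.covariates)
        design = design.reindex(columns=self.design_columns, fill_value=0.0)
        beta = self.summary["coef"].reindex(self.design_columns).to_numpy()
        return pd.Series(design.to_numpy() @ beta, index=records.index)


def cox_fit(records: pd.DataFrame, covariates: list[str]) -> CoxFit:
    """Multivariable Cox PH fit with Efron ties and Wald confidence intervals.

    Raises on non-convergence or complete separation (lifelines' convergence
    diagnostics are re-raised with the covariate list for context).
    """
    if not covariates:
        raise ValueError("empty covariate list")
    if records["event"].sum() == 0:
        raise ValueError("no events")
    design, _ = encode_covariates(records, covariates)
    df = design.copy()
    df["time_months"] = records["time_months"].to_numpy()
    df["event"] = records["event"].to_numpy()
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time_months", event_col="event")
    except Exception as exc:  # convergence / separation
        raise RuntimeError(
            f"Cox fit failed for covariates {covariates}: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame({
        "coef": s["coef"],
        "se": s["se(coef)"],
        "hr": np.exp(s["coef"]),
        "hr_ci_low": np.exp(s["coef"] - 1.96 * s["se(coef)"]),
        "hr_ci_high": np.exp(s["coef"] + 1.96 * s["se(coef)"]),
        "p": s["p"],
    })
    k = len(summary)
    ll = float(cph.log_likelihood_)
    return CoxFit(covariates=list(covariates), summary=summary,
                  log_likelihood=ll, n_params=k, aic=-2.0 * ll + 2.0 * k,
                  n=len(records), n_events=int(records["event"].sum()),
                  concordance=float(cph.concordance_index_),
                  design_columns=list(design.columns), _fitter=cph)


def univariable_screen(records: pd.DataFrame, covariates: list[str],
                       alpha: float = 0.05) -> list[str]:
    """Single-covariate Cox screen: keep factors with any Wald P < alpha.

    A factor whose fit fails (e.g. separation) is excluded with a warning.
    """
    kept = []
    for cov in covariates:
        try:
            fit = cox_fit(records, [cov])
        except (RuntimeError, ValueError) as exc:
            warnings.warn(f"univariable fit failed for {cov!r}: {exc}")
            continue
        if (fit.summary["p"] < alpha).any():
            kept.append(cov)
    return kept


def stepwise_aic(records: pd.DataFrame, candidates: list[str]) -> CoxFit:
    """Backward AIC elimination from a joint fit of all candidates.

    Repeatedly drops the covariate whose removal lowers the AIC most; stops
    when no removal improves the AIC. An AIC tie drops the later-listed
    covariate. Deterministic given the candidate order.
    """
    if not candidates:
        raise ValueError("empty candidate set")
    current = list(candidates)
    fit = cox_fit(records, current)
    while len(current) > 1:
        best_fit, best_drop = None, None
        for i, cov in enumerate(current):
            reduced = [c for c in current if c != cov]
            try:
                f = cox_fit(records, reduced)
            except (RuntimeError, ValueError):
                continue
            # strict <= so later-listed ties win the drop
            if best_fit is None or f.aic <= best_fit.aic:
                best_fit, best_drop = f, cov
        if best_fit is not None and best_fit.aic < fit.aic:
            current.remove(best_drop)
            fit = best_fit
        else:
            break
    return fit


def likelihood_ratio_test(full: CoxFit, reduced: CoxFit,
                          tol: float = 1e-8) -> tuple[float, float]:
    """LRT of nested Cox fits; returns (statistic, p-value).

    The statistic is ``2 * (logL_full - logL_reduced)`` on a chi-square with
    df equal to the parameter-count difference. A reduced model fitting
    better than the full one (beyond tolerance) violates nesting.
    """
    from scipy import stats
    stat = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    if stat < -tol:
        raise ValueError("models are not nested: reduced logL exceeds full")
    stat = max(stat, 0.0)
    df = full.n_params - reduced.n_params
    if df <= 0:
        return stat, 1.0 if stat == 0 else float("nan")
    return float(stat), float(stats.chi2.sf(stat, df))


def c_index(records: pd.DataFrame, scores: pd.Series,
            n_boot: int = 2000, seed: int = 0,
            ci: bool = True) -> tuple[float, tuple[float, float]]:
    """Harrell's concordance of a risk score, with percentile bootstrap CI.

    Among usable pairs (the shorter observed time carries an event), a pair
    is concordant when the higher risk score belongs to the shorter time;
    tied scores count 1/2. The CI resamples patients with replacement
    (``n_boot`` draws, seeded).
    """
    t = records["time_months"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=int)
    s = scores.loc[records.index].to_numpy(dtype=float) \
        if scores.index.equals(records.index) or set(records.index) <= set(scores.index) \
        else np.asarray(scores, dtype=float)
    if e.sum() == 0:
        raise ValueError("no usable pairs: no events")
    value = float(_ll_concordance(t, -s, e))
    if not ci:
        return value, (float("nan"), float("nan"))
    rng = np.random.default_rng(seed)
    n = len(t)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            boot[b] = _ll_concordance(t[idx], -s[idx], e[idx])
        except ZeroDivisionError:   # resample without admissible pairs
            boot[b] = np.nan
    lo, hi = np.nanpercentile(boot, [2.5, 97.5])
    return value, (float(lo), float(hi))


def time_dependent_auc(records: pd.DataFrame, scores: pd.Series,
                       horizon: float = 60.0,
                       grid: np.ndarray | None = None,
                       ) -> tuple[float, pd.DataFrame]:
    """IPCW cumulative/dynamic AUC(t) along a grid and at the horizon.

    Cases at t are subjects with an event by t, controls those event-free
    beyond t; inverse-probability-of-censoring weights come from the
    Kaplan-Meier estimate of the censoring distribution on the same records.
    Grid points outside the evaluable follow-up range are dropped with a
    warning.
    """
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    t = records["time_months"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=int).astype(bool)
    s = np.asarray(scores.loc[records.index] if hasattr(scores, "loc")
                   else scores, dtype=float)
    if grid is None:
        grid = np.arange(12.0, horizon + 1e-9, 6.0)
    grid = np.asarray(sorted(set(np.append(grid, horizon))), dtype=float)

    tmin = t[e].min() if e.any() else np.inf
    tmax = t.max()
    ok = (grid > tmin) & (grid < tmax)
    if not ok.all():
        warnings.warn("grid points outside evaluable range dropped")
    grid = grid[ok]
    if grid.size == 0:
        raise ValueError("no evaluable grid points within follow-up")
    y = Surv.from_arrays(e, t)
    aucs, _ = cumulative_dynamic_auc(y, y, s, grid)
    table = pd.DataFrame({"time": grid, "auc": aucs})
    at_h = table.loc[np.isclose(table["time"], horizon), "auc"]
    value = float(at_h.iloc[0]) if len(at_h) else float("nan")
    return value, table
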