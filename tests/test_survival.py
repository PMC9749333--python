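"""Survival machinery: KM, log-rank, Cox, stepwise AIC, C-index, AUC(t)."""

import numpy as np
import pandas as pd
import pytest

from mpis.survival import (c_index, cox_fit, km_estimate,
                           likelihood_ratio_test, logrank_test, stepwise_aic,
                           time_dependent_auc, univariable_screen)


def _records(times, events, **covs):
    return pd.DataFrame({"time_months": times, "event": events, **covs})


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_no_events_flat_at_one():
    rec = _records([3.0, 5.0, 7.0], [0, 0, 0])
    km = km_estimate(rec)["all"]
    assert (km["survival"] == 1.0).all()


def test_km_all_events_steps():
    rec = _records([1.0, 2.0, 3.0], [1, 1, 1])
    km = km_estimate(rec)["all"]
    steps = km.loc[km["deaths"] > 0, "survival"].tolist()
    assert steps == pytest.approx([2 / 3, 1 / 3, 0.0])


def test_km_toy_set_matches_hand_product():
    # times 1,2+,3,4,4,5+: S = 5/6 * 3/4 * 1/3 after the tied deaths at 4
    rec = _records([1, 2, 3, 4, 4, 5], [1, 0, 1, 1, 1, 0])
    km = km_estimate(rec)["all"].set_index("time")
    assert km.loc[1, "survival"] == pytest.approx(5 / 6)
    assert km.loc[3, "survival"] == pytest.approx(5 / 6 * 3 / 4)
    assert km.loc[4, "survival"] == pytest.approx(5 / 6 * 3 / 4 * 1 / 3)
    assert (np.diff(km["survival"]) <= 1e-12).all()  # non-increasing


def test_km_uncensored_equals_empirical_survivor():
    rng = np.random.default_rng(2)
    t = rng.exponential(10, 40)
    rec = _records(t, np.ones(40, dtype=int))
    km = km_estimate(rec)["all"]
    for _, row in km.iterrows():
        assert row["survival"] == pytest.approx((t > row["time"]).mean())


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

def test_logrank_identical_groups_is_null():
    base = _records([2, 4, 6, 8], [1, 1, 0, 1])
    dup = pd.concat([base.assign(risk_group="a"), base.assign(risk_group="b")])
    chi2, p = logrank_test(dup)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_logrank_toy_matches_oe_table():
    """Six-subject toy set against an explicit O/E/V tabulation."""
    rec = _records([1, 3, 4, 2, 4, 5], [1, 1, 0, 0, 1, 0],
                   risk_group=list("aaabbb"))
    # pooled event times 1,3,4; hand tables:
    # t=1: N=6, Na=3, d=1 -> E=0.5, V=1*5/5 * 9/36        = 0.25
    # t=3: N=4, Na=2, d=1 -> E=0.5, V=1*3/3 * 4/16        = 0.25
    # t=4: N=3, Na=1, d=1 -> E=1/3, V=1*2/2 * 2/9         = 2/9
    O_a, E_a, V = 2.0, 0.5 + 0.5 + 1 / 3, 0.25 + 0.25 + 2 / 9
    expected = (O_a - E_a) ** 2 / V
    chi2, p = logrank_test(rec)
    assert chi2 == pytest.approx(expected, rel=1e-9)


def test_logrank_no_events_errors():
    rec = _records([1, 2], [0, 0], risk_group=["a", "b"])
    with pytest.raises(ValueError, match="events"):
        logrank_test(rec)


# ---------------------------------------------------------------------------
# Cox fits
# ---------------------------------------------------------------------------

def _exp_cohort(n, beta, seed, censor_scale=120.0):
    rng = np.random.default_rng(seed)
    g = rng.integers(0, 2, n).astype(float)
    t_ev = rng.exponential(1 / (0.02 * np.exp(beta * g)))
    t_c = np.minimum(rng.exponential(censor_scale, n), 120.0)
    return _records(np.minimum(t_ev, t_c), (t_ev <= t_c).astype(int), grp=g)


def test_cox_null_covariate_near_zero():
    rec = _exp_cohort(2000, 0.0, 0)
    fit = cox_fit(rec, ["grp"])
    assert abs(fit.summary.loc["grp", "coef"]) < 0.1
    assert fit.summary.loc["grp", "hr_ci_low"] < 1 < fit.summary.loc["grp", "hr_ci_high"]


def test_cox_recovers_hr_two():
    rec = _exp_cohort(2000, np.log(2.0), 1)
    fit = cox_fit(rec, ["grp"])
    assert 1.8 <= fit.summary.loc["grp", "hr"] <= 2.2


def test_cox_duplication_invariance():
    # exact under Breslow ties; Efron's tie correction perturbs it slightly
    rec = _exp_cohort(150, np.log(2.0), 2)
    fit1 = cox_fit(rec, ["grp"])
    fit2 = cox_fit(pd.concat([rec, rec], ignore_index=True), ["grp"])
    assert fit2.summary.loc["grp", "coef"] == pytest.approx(
        fit1.summary.loc["grp", "coef"], abs=0.01)


def test_cox_categorical_reference_coding():
    rng = np.random.default_rng(3)
    n = 400
    stage = rng.choice(["I", "II", "III"], n, p=[0.5, 0.3, 0.2])
    lp = np.where(stage == "II", 0.5, 0.0) + np.where(stage == "III", 1.0, 0.0)
    t = rng.exponential(1 / (0.02 * np.exp(lp)))
    rec = _records(t, np.ones(n, int), tnm_stage=stage)
    fit = cox_fit(rec, ["tnm_stage"])
    assert list(fit.summary.index) == ["tnm_stage[II]", "tnm_stage[III]"]
    assert fit.summary.loc["tnm_stage[III]", "coef"] > \
        fit.summary.loc["tnm_stage[II]", "coef"]


def test_univariable_screen_alpha_one_keeps_all():
    rec = _exp_cohort(100, 0.3, 4)
    rec["noise"] = np.random.default_rng(5).standard_normal(len(rec))
    kept = univariable_screen(rec, ["grp", "noise"], alpha=1.0)
    assert kept == ["grp", "noise"]


def test_univariable_screen_retains_strong_covariate():
    hits = 0
    for seed in range(10):
        rec = _exp_cohort(500, np.log(3.0), 100 + seed)
        rng = np.random.default_rng(200 + seed)
        rec["noise"] = rng.standard_normal(len(rec))
        kept = univariable_screen(rec, ["grp", "noise"])
        hits += "grp" in kept
    assert hits >= 9


def test_stepwise_keeps_strong_drops_null():
    kept_strong, kept_null = 0, 0
    for seed in range(10):
        rec = _exp_cohort(500, np.log(3.0), 300 + seed)
        rng = np.random.default_rng(400 + seed)
        rec["noise"] = rng.standard_normal(len(rec))
        fit = stepwise_aic(rec, ["grp", "noise"])
        kept_strong += "grp" in fit.covariates
        kept_null += "noise" in fit.covariates
    assert kept_strong == 10
    assert kept_null <= 3


def test_stepwise_single_strong_candidate_kept():
    rec = _exp_cohort(500, np.log(3.0), 6)
    fit = stepwise_aic(rec, ["grp"])
    assert fit.covariates == ["grp"]


def test_stepwise_aic_never_beaten_by_submodels():
    rec = _exp_cohort(300, np.log(2.0), 7)
    rng = np.random.default_rng(8)
    rec["n1"] = rng.standard_normal(len(rec))
    rec["n2"] = rng.standard_normal(len(rec))
    final = stepwise_aic(rec, ["grp", "n1", "n2"])
    full = cox_fit(rec, ["grp", "n1", "n2"])
    assert final.aic <= full.aic + 1e-9
    # logL of the larger model bounds the final model's from above
    assert full.log_likelihood >= final.log_likelihood - 1e-9


# ---------------------------------------------------------------------------
# likelihood ratio test
# ---------------------------------------------------------------------------

def test_lrt_identical_models_p_one():
    rec = _exp_cohort(200, np.log(2.0), 9)
    fit = cox_fit(rec, ["grp"])
    stat, p = likelihood_ratio_test(fit, fit)
    assert stat == pytest.approx(0.0, abs=1e-12) and p == 1.0


def test_lrt_null_addition_p_uniform():
    """Adding pure noise gives approximately uniform LRT p-values."""
    from scipy import stats
    ps = []
    for seed in range(60):
        rec = _exp_cohort(120, np.log(2.0), 1000 + seed)
        rng = np.random.default_rng(2000 + seed)
        rec["noise"] = rng.standard_normal(len(rec))
        full = cox_fit(rec, ["grp", "noise"])
        red = cox_fit(rec, ["grp"])
        ps.append(likelihood_ratio_test(full, red)[1])
    assert stats.kstest(ps, "uniform").pvalue > 0.01


def test_lrt_detects_nesting_violation():
    rec = _exp_cohort(200, np.log(2.0), 10)
    full = cox_fit(rec, ["grp"])
    rng = np.random.default_rng(11)
    rec2 = rec.copy()
    rec2["other"] = rng.standard_normal(len(rec))
    bigger = cox_fit(rec2, ["grp", "other"])
    with pytest.raises(ValueError, match="nested"):
        likelihood_ratio_test(full, bigger)  # arguments swapped


# ---------------------------------------------------------------------------
# concordance
# ---------------------------------------------------------------------------

def cindex_oracle(time, event, score):
    """Exhaustive enumeration of usable pairs."""
    num = den = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if score[i] > score[j]:
                    num += 1
                elif score[i] == score[j]:
                    num += 0.5
    return num / den


def test_cindex_perfect_and_reversed():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    rec = _records(t, [1, 1, 1, 1])
    s = pd.Series([4.0, 3.0, 2.0, 1.0], index=rec.index)
    assert c_index(rec, s, ci=False)[0] == 1.0
    assert c_index(rec, -s, ci=False)[0] == 0.0


def test_cindex_antisymmetry_and_random_half():
    rng = np.random.default_rng(12)
    rec = _records(rng.exponential(10, 200), np.ones(200, int))
    s = pd.Series(rng.standard_normal(200), index=rec.index)
    c_pos = c_index(rec, s, ci=False)[0]
    c_neg = c_index(rec, -s, ci=False)[0]
    assert c_pos + c_neg == pytest.approx(1.0)
    assert abs(c_pos - 0.5) < 0.08


def test_cindex_toy_censored_matches_pair_oracle():
    t = np.array([2.0, 4.0, 3.0, 5.0, 1.0])
    e = np.array([1, 0, 1, 1, 1])
    rec = _records(t, e)
    s = pd.Series([0.9, 0.1, 0.4, 0.2, 0.7], index=rec.index)
    value, (lo, hi) = c_index(rec, s, n_boot=200, seed=0)
    assert value == pytest.approx(cindex_oracle(t, e, s.to_numpy()))
    assert lo <= value <= hi


def test_cindex_bootstrap_ci_is_seeded():
    rng = np.random.default_rng(13)
    rec = _records(rng.exponential(10, 60), rng.integers(0, 2, 60))
    rec.loc[0, "event"] = 1
    s = pd.Series(rng.standard_normal(60), index=rec.index)
    a = c_index(rec, s, n_boot=100, seed=5)
    b = c_index(rec, s, n_boot=100, seed=5)
    assert a == b


# ---------------------------------------------------------------------------
# time-dependent AUC
# ---------------------------------------------------------------------------

def test_auc_uncensored_equals_plain_roc():
    from sklearn.metrics import roc_auc_score
    rng = np.random.default_rng(14)
    n = 400
    score = rng.standard_normal(n)
    t = rng.exponential(1 / (0.02 * np.exp(score)))
    rec = _records(t, np.ones(n, int))
    auc, grid = time_dependent_auc(rec, pd.Series(score, index=rec.index),
                                   horizon=60.0)
    plain = roc_auc_score((t <= 60.0).astype(int), score)
    assert auc == pytest.approx(plain, abs=1e-9)


def test_auc_perfect_ordering_is_one():
    t = np.linspace(1, 100, 50)
    rec = _records(t, np.ones(50, int))
    score = pd.Series(-t, index=rec.index)   # higher risk <-> earlier event
    auc, grid = time_dependent_auc(rec, score, horizon=60.0)
    assert auc == pytest.approx(1.0)
    assert np.allclose(grid["auc"], 1.0)


def test_auc_null_score_near_half():
    vals = []
    for seed in range(30):
        rng = np.random.default_rng(3000 + seed)
        t = rng.exponential(60, 150)
        c = np.minimum(rng.exponential(180, 150), 120)
        rec = _records(np.minimum(t, c), (t <= c).astype(int))
        s = pd.Series(rng.standard_normal(150), index=rec.index)
        auc, _ = time_dependent_auc(rec, s, horizon=60.0)
        vals.append(auc)
    assert abs(np.mean(vals) - 0.5) < 0.03
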