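"""Survival-statistics toolkit against hand computations and independent
implementations (lifelines / scikit-survival serve as cross-check oracles
only; every statistic under test is computed by this package)."""

import numpy as np
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index
from scipy import stats as sps

from ildgapc import (
    auc_time_dependent,
    compare_groups,
    cox_aic,
    cox_univariate,
    harrell_c,
    km_estimate,
    logrank_test,
)

import pandas as pd


# --------------------------------------------------------------------- KM

def test_km_all_censored_is_flat_one():
    km = km_estimate([5.0, 8.0, 9.0], [0, 0, 0])
    assert km.times.size == 0
    assert km.survival_at(7.0) == 1.0


def test_km_hand_product_limit_all_events():
    km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
    np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
    np.testing.assert_allclose(km.n_at_risk, [3, 2, 1])


def test_km_censoring_shrinks_risk_set():
    km = km_estimate([1.0, 2.0], [0, 1])
    np.testing.assert_allclose(km.survival, [0.0])
    np.testing.assert_allclose(km.n_at_risk, [1])


def test_km_no_censoring_equals_empirical_survival():
    rng = np.random.default_rng(0)
    t = rng.exponential(10, 50)
    km = km_estimate(t, np.ones(50, dtype=int))
    for q in [np.min(t), np.median(t), np.percentile(t, 90)]:
        assert km.survival_at(q) == pytest.approx(np.mean(t > q))


def test_km_matches_lifelines(censored_survival_sample):
    time, event, _ = censored_survival_sample
    km = km_estimate(time, event)
    kmf = KaplanMeierFitter().fit(time, event)
    theirs = kmf.survival_function_at_times(km.times).to_numpy()
    np.testing.assert_allclose(km.survival, theirs, rtol=1e-10)


def test_km_greenwood_variance_hand_value():
    # S at t=2 for (1,2,3 events): S=1/3, var = S^2 (1/(3*2) + 1/(2*1))
    km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
    assert km.variance[1] == pytest.approx((1 / 3) ** 2 * (1 / 6 + 1 / 2))


# ---------------------------------------------------------------- log-rank

def test_logrank_identical_groups_is_null():
    t = [1.0, 2.0, 3.0, 4.0]
    e = [1, 0, 1, 1]
    res = logrank_test(t + t, e + e, ["a"] * 4 + ["b"] * 4)
    assert res.chi_square == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_logrank_matches_lifelines(censored_survival_sample):
    time, event, score = censored_survival_sample
    group = np.digitize(score, [-0.5, 0.5])  # three groups
    res = logrank_test(time, event, group)
    theirs = multivariate_logrank_test(time, group, event)
    assert res.chi_square == pytest.approx(theirs.test_statistic, rel=1e-8)
    assert res.p == pytest.approx(theirs.p_value, rel=1e-8)
    assert res.df == 2


def test_logrank_invariant_under_relabeling_and_time_transform(
    censored_survival_sample,
):
    time, event, score = censored_survival_sample
    group = (score > 0).astype(int)
    base = logrank_test(time, event, group)
    relabeled = logrank_test(time, event, np.where(group == 0, "z", "a"))
    warped = logrank_test(np.log1p(time), event, group)
    assert relabeled.chi_square == pytest.approx(base.chi_square, rel=1e-12)
    assert warped.chi_square == pytest.approx(base.chi_square, rel=1e-12)


def test_logrank_requires_two_groups_and_an_event():
    with pytest.raises(ValueError):
        logrank_test([1.0, 2.0], [1, 1], ["a", "a"])
    with pytest.raises(ValueError):
        logrank_test([1.0, 2.0], [0, 0], ["a", "b"])


def test_logrank_score_test_identity_no_ties():
    """Without tied event times, the 2-group log-rank chi-square equals the
    Cox partial-likelihood score test on the binary group covariate."""
    rng = np.random.default_rng(3)
    time = rng.exponential(10, 40)
    event = rng.random(40) < 0.7
    x = (rng.random(40) < 0.5).astype(float)
    from ildgapc.stats import _cox_loglik_grad_hess

    _, grad, info = _cox_loglik_grad_hess(
        0.0, time, event.astype(int), x - x.mean(), "efron"
    )
    lr = logrank_test(time, event.astype(int), x)
    assert grad**2 / info == pytest.approx(lr.chi_square, abs=1e-6)


# --------------------------------------------------------------------- Cox

def test_cox_matches_lifelines_efron(censored_survival_sample):
    time, event, score = censored_survival_sample
    df = pd.DataFrame({"t": time, "e": event, "x": score})
    fit = cox_univariate(time, event, score, ties="efron")
    cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
    # lifelines stops at a looser gradient tolerance than our Newton solver
    assert fit.beta == pytest.approx(float(cph.params_["x"]), abs=1e-4)
    assert fit.se == pytest.approx(float(cph.standard_errors_["x"]), abs=1e-4)
    assert fit.log_likelihood == pytest.approx(cph.log_likelihood_, abs=1e-6)
    assert fit.log_likelihood >= cph.log_likelihood_ - 1e-10
    assert fit.hr == pytest.approx(float(np.exp(cph.params_["x"])), rel=1e-4)


def test_cox_breslow_matches_sksurv(censored_survival_sample):
    from sksurv.linear_model import CoxPHSurvivalAnalysis
    from sksurv.util import Surv

    time, event, score = censored_survival_sample
    fit = cox_univariate(time, event, score, ties="breslow")
    est = CoxPHSurvivalAnalysis(ties="breslow", tol=1e-12).fit(
        score.reshape(-1, 1), Surv.from_arrays(event.astype(bool), time)
    )
    assert fit.beta == pytest.approx(float(est.coef_[0]), abs=1e-6)


def test_cox_reparameterization_invariance(censored_survival_sample):
    time, event, score = censored_survival_sample
    f1 = cox_univariate(time, event, score)
    f2 = cox_univariate(time, event, 2.0 * score)
    assert f2.beta == pytest.approx(f1.beta / 2, rel=1e-6)
    assert f2.log_likelihood == pytest.approx(f1.log_likelihood, abs=1e-8)
    assert cox_aic(f2) == pytest.approx(cox_aic(f1), abs=1e-8)


def test_cox_error_conditions():
    with pytest.raises(ValueError, match="constant"):
        cox_univariate([1.0, 2.0, 3.0], [1, 1, 0], [2.0, 2.0, 2.0])
    with pytest.raises(ValueError, match="event"):
        cox_univariate([1.0, 2.0], [0, 0], [1.0, 2.0])


def test_cox_perfect_separation_is_bounded():
    time = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
    event = np.array([1, 1, 1, 1, 1, 1])
    x = np.array([1.0, 1.0, 1.0, 0.0, 0.0, 0.0])
    with pytest.warns(RuntimeWarning, match="monotone"):
        fit = cox_univariate(time, event, x)
    assert np.isfinite(fit.beta)


def test_cox_aic_identity(censored_survival_sample):
    time, event, score = censored_survival_sample
    fit = cox_univariate(time, event, score)
    assert cox_aic(fit) - (-2 * fit.log_likelihood) == pytest.approx(2.0)
    # informative score: AIC beats the null model's -2*loglik(0)
    assert cox_aic(fit) < -2 * fit.log_likelihood_null


# -------------------------------------------------------------- concordance

def _harrell_oracle(time, event, score):
    conc = usable = 0.0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j or event[i] != 1:
                continue
            if not (time[j] > time[i] or (time[j] == time[i] and event[j] == 0)):
                continue
            usable += 1
            if score[i] > score[j]:
                conc += 1
            elif score[i] == score[j]:
                conc += 0.5
    return conc / usable


def test_harrell_constant_score_is_half():
    assert harrell_c([1.0, 2.0, 3.0], [1, 1, 1], [5.0, 5.0, 5.0]) == 0.5


def test_harrell_perfect_antirank_is_one():
    t = [1.0, 2.0, 3.0, 4.0]
    assert harrell_c(t, [1, 1, 1, 1], [4.0, 3.0, 2.0, 1.0]) == 1.0


def test_harrell_six_subject_fixture_matches_enumeration():
    time = [2.0, 4.0, 4.0, 6.0, 7.0, 9.0]
    event = [1, 1, 0, 1, 0, 1]
    score = [3.0, 2.0, 2.0, 1.0, 2.5, 0.5]
    assert harrell_c(time, event, score) == _harrell_oracle(time, event, score)


def test_harrell_negation_symmetry_and_lifelines(censored_survival_sample):
    time, event, score = censored_survival_sample
    c = harrell_c(time, event, score)
    assert harrell_c(time, event, -score) == pytest.approx(1 - c)
    # lifelines orients scores as survival predictions, hence -score
    assert c == pytest.approx(concordance_index(time, -score, event))


# ----------------------------------------------------- time-dependent AUC

def test_auc_perfect_separation_no_censoring():
    time = np.array([1.0, 2.0, 3.0, 20.0, 30.0, 40.0])
    event = np.ones(6, dtype=int)
    score = np.array([6.0, 5.0, 4.0, 1.0, 2.0, 0.5])
    assert auc_time_dependent(time, event, score, 10.0) == 1.0


def test_auc_reduces_to_mann_whitney_without_censoring():
    rng = np.random.default_rng(5)
    n = 60
    score = rng.normal(size=n)
    time = rng.exponential(30 * np.exp(-score))
    event = np.ones(n, dtype=int)
    horizon = 25.0
    case = time <= horizon
    u = sps.mannwhitneyu(score[case], score[~case]).statistic
    mw_auc = u / (case.sum() * (~case).sum())
    assert auc_time_dependent(time, event, score, horizon) == pytest.approx(
        mw_auc, abs=1e-12
    )


def test_auc_monotone_transform_invariance(censored_survival_sample):
    time, event, score = censored_survival_sample
    horizon = float(np.percentile(time, 60))
    a = auc_time_dependent(time, event, score, horizon)
    b = auc_time_dependent(time, event, np.exp(3 * score), horizon)
    assert a == pytest.approx(b, abs=1e-12)


def test_auc_close_to_sksurv_ipcw_estimator(censored_survival_sample):
    from sksurv.metrics import cumulative_dynamic_auc
    from sksurv.util import Surv

    time, event, score = censored_survival_sample
    horizon = float(np.percentile(time, 50))
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    theirs, _ = cumulative_dynamic_auc(y, y, score, [horizon])
    ours = auc_time_dependent(time, event, score, horizon)
    assert ours == pytest.approx(float(theirs[0]), abs=0.02)


def test_auc_error_conditions():
    with pytest.raises(ValueError):
        auc_time_dependent([5.0, 6.0], [1, 1], [1.0, 2.0], 1.0)  # no events by t
    with pytest.raises(ValueError):
        auc_time_dependent([0.5, 0.6], [1, 1], [1.0, 2.0], 1.0)  # no controls


# ------------------------------------------------------- group comparisons

def test_chi_square_balanced_table_is_null():
    g1 = ["m"] * 10 + ["f"] * 10
    g2 = ["m"] * 10 + ["f"] * 10
    assert compare_groups([g1, g2], "categorical") == pytest.approx(1.0)


def test_chi_square_matches_closed_form_pearson():
    # 2x2 cells: males/females 49/8 vs 66/51
    g1 = ["m"] * 49 + ["f"] * 8
    g2 = ["m"] * 66 + ["f"] * 51
    a, b, c, d = 49, 8, 66, 51
    n = a + b + c + d
    chi2 = n * (a * d - b * c) ** 2 / (
        (a + b) * (c + d) * (a + c) * (b + d)
    )
    expected_p = float(sps.chi2.sf(chi2, 1))
    assert compare_groups([g1, g2], "categorical") == pytest.approx(
        expected_p, rel=1e-12
    )
    assert expected_p < 0.001


def test_wilcoxon_identical_samples():
    x = [1.0, 2.0, 3.0, 4.0]
    assert compare_groups([x, list(x)], "continuous") == pytest.approx(1.0)


def test_kruskal_for_three_groups():
    rng = np.random.default_rng(8)
    gs = [rng.normal(loc, 1.0, 30) for loc in (0.0, 0.0, 2.0)]
    p = compare_groups(gs, "continuous")
    assert p == pytest.approx(float(sps.kruskal(*gs).pvalue))
    assert p < 0.01


def test_compare_groups_rejects_empty():
    with pytest.raises(ValueError):
        compare_groups([[1.0], []], "continuous")
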