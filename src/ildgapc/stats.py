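"""Right-censored survival statistics, implemented from the defining formulas.

This module carries the statistical machinery used to compare prognostic
scores on censored follow-up data:

* Kaplan–Meier product-limit estimator with Greenwood variance,
* k-sample log-rank test (asymptotic chi-square or label-permutation p),
* univariate Cox proportional-hazards regression (Newton–Raphson on the
  partial likelihood, Efron or Breslow tie handling) and its AIC,
* Harrell's concordance index,
* cumulative/dynamic time-dependent ROC AUC with inverse-probability-of-
  censoring weights (IPCW) from the reverse Kaplan–Meier estimate of the
  censoring distribution,
* nonparametric group comparisons (Pearson chi-square, Wilcoxon rank-sum,
  Kruskal–Wallis).

Conventions: times are positive and in days; ``event`` is 1 for an observed
event and 0 for right censoring; ties between events and censorings at the
same time are resolved events-first (a subject censored at *t* is still at
risk for events at *t*).  Scores are risk scores: higher score is expected
to mean earlier failure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "KMCurve",
    "LogrankResult",
    "CoxResult",
    "km_estimate",
    "logrank_test",
    "cox_univariate",
    "cox_aic",
    "harrell_c",
    "auc_time_dependent",
    "compare_groups",
]

_MONOTONE_BETA_BOUND = 15.0


def _as_sample(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("empty sample")
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    if np.any(time <= 0):
        raise ValueError("times must be positive")
    if not np.all((event == 0) | (event == 1)):
        raise ValueError("event indicators must be 0/1")
    return time, event


# ---------------------------------------------------------------------------
# Kaplan–Meier
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate evaluated after each event time."""

    times: np.ndarray        # distinct event times, ascending
    survival: np.ndarray     # S(t) just after each event time
    variance: np.ndarray     # Greenwood variance of S(t) per step
    n_at_risk: np.ndarray    # risk-set size at each event time
    n_events: np.ndarray     # events at each event time

    def survival_at(self, t, side: str = "right") -> np.ndarray:
        """Step-function value S(t); ``side='left'`` gives the limit S(t-)."""
        idx = np.searchsorted(self.times, np.atleast_1d(t), side=side)
        s = np.concatenate(([1.0], self.survival))
        out = s[idx]
        return out if np.ndim(t) else float(out[0])


def km_estimate(time, event) -> KMCurve:
    """Kaplan–Meier estimator S(t) = prod_{t_i <= t} (1 - d_i / n_i).

    The Greenwood variance is
    ``S(t)^2 * sum_{t_i <= t} d_i / (n_i (n_i - d_i))``.
    """
    time, event = _as_sample(time, event)
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]

    event_times = np.unique(time[event == 1])
    if event_times.size == 0:
        return KMCurve(
            times=event_times,
            survival=np.empty(0),
            variance=np.empty(0),
            n_at_risk=np.empty(0, dtype=int),
            n_events=np.empty(0, dtype=int),
        )
    # risk set: all subjects with time >= t (censored at t included: events first)
    n_at_risk = time.size - np.searchsorted(t_sorted, event_times, side="left")
    ev_sorted = np.sort(time[event == 1])
    d = (
        np.searchsorted(ev_sorted, event_times, side="right")
        - np.searchsorted(ev_sorted, event_times, side="left")
    )
    surv = np.cumprod(1.0 - d / n_at_risk)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = np.where(
            n_at_risk > d, d / (n_at_risk * (n_at_risk - d)), 0.0
        )
    var = surv**2 * np.cumsum(gw_terms)
    return KMCurve(event_times, surv, var, n_at_risk, d)


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    df: int
    p: float
    observed: np.ndarray   # events per group
    expected: np.ndarray   # expected events per group under H0


def _logrank_statistic(time, event, codes, k) -> tuple[float, np.ndarray, np.ndarray]:
    """Chi-square statistic from observed-minus-expected with hypergeometric
    variance, summed over distinct event times."""
    event_times = np.unique(time[event == 1])
    # per-group risk counts at each event time via sorted per-group times
    n_ij = np.empty((event_times.size, k))
    d_ij = np.empty((event_times.size, k))
    for g in range(k):
        tg = np.sort(time[codes == g])
        n_ij[:, g] = tg.size - np.searchsorted(tg, event_times, side="left")
        eg = np.sort(time[(codes == g) & (event == 1)])
        d_ij[:, g] = (
            np.searchsorted(eg, event_times, side="right")
            - np.searchsorted(eg, event_times, side="left")
        )
    n_j = n_ij.sum(axis=1)
    d_j = d_ij.sum(axis=1)
    p_ij = n_ij / n_j[:, None]
    observed = d_ij.sum(axis=0)
    expected = (d_j[:, None] * p_ij).sum(axis=0)
    u = observed - expected
    with np.errstate(divide="ignore", invalid="ignore"):
        c_j = np.where(n_j > 1, d_j * (n_j - d_j) / (n_j - 1), 0.0)
    # V = sum_j c_j (diag(p_j) - p_j p_j')
    v = np.einsum("j,jg->g", c_j, p_ij) * np.eye(k) - np.einsum(
        "j,jg,jh->gh", c_j, p_ij, p_ij
    )
    vr = v[:-1, :-1]
    ur = u[:-1]
    stat = float(ur @ np.linalg.pinv(vr) @ ur)
    return max(stat, 0.0), observed, expected


def logrank_test(
    time,
    event,
    group,
    *,
    p_method: str = "asymptotic",
    n_permutations: int = 10_000,
    rng=None,
) -> LogrankResult:
    """k-sample log-rank test.

    At each distinct event time the observed events per group are compared
    with their expectation under the null (events allocated to groups in
    proportion to the risk sets), with the multivariate hypergeometric
    variance; the quadratic form is referred to a chi-square with k-1
    degrees of freedom.  ``p_method="permutation"`` instead computes the
    p-value by uniformly permuting group labels (``n_permutations`` draws,
    add-one estimator), which is preferable for very small samples.
    """
    time, event = _as_sample(time, event)
    group = np.asarray(group)
    labels, codes = np.unique(group, return_inverse=True)
    k = labels.size
    if k < 2:
        raise ValueError("log-rank test needs at least two non-empty groups")
    if event.sum() == 0:
        raise ValueError("log-rank test needs at least one event")

    stat, observed, expected = _logrank_statistic(time, event, codes, k)
    if p_method == "asymptotic":
        p = float(sps.chi2.sf(stat, k - 1))
    elif p_method == "permutation":
        rng = np.random.default_rng(rng)
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(codes)
            s, _, _ = _logrank_statistic(time, event, perm, k)
            exceed += s >= stat - 1e-12
        p = (1 + exceed) / (1 + n_permutations)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return LogrankResult(stat, k - 1, p, observed, expected)


# ---------------------------------------------------------------------------
# Cox proportional hazards (univariate)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoxResult:
    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    log_likelihood: float        # maximised log partial likelihood
    log_likelihood_null: float   # at beta = 0
    n: int
    n_events: int
    converged: bool


def _cox_loglik_grad_hess(beta, time, event, x, ties):
    """Log partial likelihood and derivatives for a single covariate.

    Efron ties: for a tie group D of size d at one event time, the l-th
    factor (l = 0..d-1) uses risk sums minus the fraction l/d of the tie
    group's sums.  Breslow uses the full risk sums d times.
    """
    order = np.argsort(time, kind="stable")
    t, e, xv = time[order], event[order], x[order]
    w = np.exp(beta * xv)
    # suffix sums over the risk set (time >= t)
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w * xv)[::-1])[::-1]
    s2 = np.cumsum((w * xv * xv)[::-1])[::-1]

    ll = 0.0
    grad = 0.0
    info = 0.0
    event_times = np.unique(t[e == 1])
    for et in event_times:
        start = np.searchsorted(t, et, side="left")
        in_tie = (t == et) & (e == 1)
        d = int(in_tie.sum())
        xs = xv[in_tie]
        ws = w[in_tie]
        ll += beta * xs.sum()
        r0, r1, r2 = s0[start], s1[start], s2[start]
        if ties == "efron" and d > 1:
            t0, t1, t2 = ws.sum(), (ws * xs).sum(), (ws * xs * xs).sum()
            frac = np.arange(d) / d
            phi0 = r0 - frac * t0
            phi1 = r1 - frac * t1
            phi2 = r2 - frac * t2
        else:  # breslow, or a single event
            phi0 = np.full(d, r0)
            phi1 = np.full(d, r1)
            phi2 = np.full(d, r2)
        ll -= np.log(phi0).sum()
        m1 = phi1 / phi0
        grad += xs.sum() - m1.sum()
        info += (phi2 / phi0 - m1**2).sum()
    return ll, grad, info


def cox_univariate(
    time, event, score, *, ties: str = "efron", max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxResult:
    """Fit the Cox model h(t|x) = h0(t) exp(beta x) for a single covariate.

    Newton–Raphson with step-halving on the log partial likelihood;
    ``ties`` selects the Efron (default) or Breslow approximation.  The
    hazard ratio is exp(beta) with a Wald 95% CI and two-sided p.  A
    monotone likelihood (perfect separation) is reported with a warning
    and a bounded estimate.
    """
    time, event = _as_sample(time, event)
    x = np.asarray(score, dtype=float)
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("Cox regression needs at least one event")
    if np.ptp(x) == 0:
        raise ValueError("score is constant; the Cox coefficient is undefined")
    # center for numerical stability (leaves beta unchanged)
    xc = x - x.mean()

    ll_null, _, _ = _cox_loglik_grad_hess(0.0, time, event, xc, ties)
    beta = 0.0
    ll = ll_null
    converged = False
    for _ in range(max_iter):
        ll, grad, info = _cox_loglik_grad_hess(beta, time, event, xc, ties)
        if info <= 0:
            break
        step = grad / info
        # step-halving to guarantee likelihood ascent
        new_beta = beta + step
        for _ in range(30):
            new_ll, _, _ = _cox_loglik_grad_hess(new_beta, time, event, xc, ties)
            if new_ll >= ll - 1e-12:
                break
            new_beta = beta + (new_beta - beta) / 2
        if abs(new_beta - beta) < tol and abs(grad) < 1e-6:
            beta = new_beta
            converged = True
            break
        beta = new_beta
        if abs(beta) > _MONOTONE_BETA_BOUND:
            warnings.warn(
                "monotone partial likelihood (perfect separation); "
                "coefficient bounded",
                RuntimeWarning,
                stacklevel=2,
            )
            beta = float(np.sign(beta) * _MONOTONE_BETA_BOUND)
            break
    ll, grad, info = _cox_loglik_grad_hess(beta, time, event, xc, ties)
    se = float(1.0 / np.sqrt(info)) if info > 0 else np.inf
    z = beta / se if se > 0 and np.isfinite(se) else 0.0
    p = float(2 * sps.norm.sf(abs(z)))
    half = 1.959963984540054 * se
    with np.errstate(over="ignore"):
        ci_low, ci_high = np.exp(beta - half), np.exp(beta + half)
    return CoxResult(
        beta=float(beta),
        se=se,
        hr=float(np.exp(beta)),
        p=p,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        log_likelihood=float(ll),
        log_likelihood_null=float(ll_null),
        n=int(time.size),
        n_events=n_events,
        converged=converged,
    )


def cox_aic(fit: CoxResult, n_params: int = 1) -> float:
    """Akaike information criterion from the Cox partial likelihood:
    ``AIC = -2 * loglik + 2 * n_params``."""
    return -2.0 * fit.log_likelihood + 2.0 * n_params


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def harrell_c(time, event, score) -> float:
    """Harrell's concordance index for a risk score.

    Over all comparable pairs — the earlier time has an observed event, and
    either the times differ or the later subject is censored at the tied
    time — the pair is concordant when the failing subject carries the
    higher score; score ties count 1/2.
    """
    time, event = _as_sample(time, event)
    score = np.asarray(score, dtype=float)
    order = np.argsort(time, kind="stable")
    t, e, s = time[order], event[order], score[order]
    n = t.size
    concordant = 0.0
    usable = 0
    for i in np.flatnonzero(e == 1):
        later = (t > t[i]) | ((t == t[i]) & (e == 0))
        later[i] = False
        m = int(later.sum())
        if m == 0:
            continue
        usable += m
        sj = s[later]
        concordant += np.count_nonzero(s[i] > sj) + 0.5 * np.count_nonzero(
            s[i] == sj
        )
    if usable == 0:
        raise ValueError("no usable pairs for the concordance index")
    return concordant / usable


# ---------------------------------------------------------------------------
# time-dependent ROC AUC (cumulative/dynamic, IPCW)
# ---------------------------------------------------------------------------

def _censoring_survival(time, event) -> KMCurve:
    """Reverse Kaplan–Meier: KM of the censoring distribution, with events
    removed from the risk set before censorings at tied times."""
    time, event = _as_sample(time, event)
    cens_times = np.unique(time[event == 0])
    if cens_times.size == 0:
        return KMCurve(
            cens_times, np.empty(0), np.empty(0),
            np.empty(0, dtype=int), np.empty(0, dtype=int),
        )
    t_sorted = np.sort(time)
    ev_sorted = np.sort(time[event == 1])
    cn_sorted = np.sort(time[event == 0])
    n_at_risk = time.size - np.searchsorted(t_sorted, cens_times, side="left")
    d_events = (
        np.searchsorted(ev_sorted, cens_times, side="right")
        - np.searchsorted(ev_sorted, cens_times, side="left")
    )
    dc = (
        np.searchsorted(cn_sorted, cens_times, side="right")
        - np.searchsorted(cn_sorted, cens_times, side="left")
    )
    denom = n_at_risk - d_events  # events at t leave the risk set first
    surv = np.cumprod(np.where(denom > 0, 1.0 - dc / np.maximum(denom, 1), 1.0))
    return KMCurve(cens_times, surv, np.zeros_like(surv), n_at_risk, dc)


def auc_time_dependent(time, event, score, horizon: float) -> float:
    """Cumulative/dynamic AUC at ``horizon`` under right censoring.

    Cases are subjects with an observed event at T <= horizon, weighted
    1/G(T-); dynamic controls are subjects known event-free through the
    horizon (T > horizon, or censored exactly at the horizon under the
    events-first tie convention), weighted 1/G(horizon-), where G is the
    reverse-KM censoring survival function.  The AUC is the IPCW-weighted
    probability that a random case outscores a random control (score ties
    count 1/2).  With no censoring before the horizon all weights are equal
    and the estimate reduces to the Mann–Whitney AUC of score against
    event-by-horizon status.
    """
    time, event = _as_sample(time, event)
    score = np.asarray(score, dtype=float)
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    case = (event == 1) & (time <= horizon)
    control = (time > horizon) | ((time == horizon) & (event == 0))
    if not case.any():
        raise ValueError("no events before the horizon")
    if not control.any():
        raise ValueError("no subjects event-free through the horizon")

    g = _censoring_survival(time, event)
    g_case = g.survival_at(time[case], side="left")
    g_ctrl = g.survival_at(horizon, side="left")
    if np.any(np.asarray(g_case) <= 0) or g_ctrl <= 0:
        raise ValueError("censoring survival reached zero before the horizon")
    w_case = 1.0 / np.asarray(g_case, dtype=float)
    w_ctrl = np.full(int(control.sum()), 1.0 / float(g_ctrl))

    s_case = score[case]
    s_ctrl = score[control]
    order = np.argsort(s_ctrl, kind="stable")
    s_ctrl_sorted = s_ctrl[order]
    cum_w = np.concatenate(([0.0], np.cumsum(w_ctrl[order])))
    lo = np.searchsorted(s_ctrl_sorted, s_case, side="left")
    hi = np.searchsorted(s_ctrl_sorted, s_case, side="right")
    below = cum_w[lo]
    tied = cum_w[hi] - cum_w[lo]
    num = float(np.sum(w_case * (below + 0.5 * tied)))
    den = float(w_case.sum() * w_ctrl.sum())
    return num / den


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def compare_groups(groups, kind: str) -> float:
    """Two-sided p-value comparing k groups.

    ``kind="categorical"``: Pearson chi-square (no continuity correction)
    on the k x levels contingency table of the groups' label values.
    ``kind="continuous"``: Wilcoxon rank-sum (Mann–Whitney, normal
    approximation without continuity correction so that identical samples
    give p = 1 exactly) for k = 2, Kruskal–Wallis for k > 2.
    """
    groups = [np.asarray(g) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    if kind == "categorical":
        levels = np.unique(np.concatenate(groups))
        table = np.array(
            [[np.count_nonzero(g == lv) for lv in levels] for g in groups]
        )
        table = table[:, table.sum(axis=0) > 0]
        _, p, _, _ = sps.chi2_contingency(table, correction=False)
        return float(p)
    if kind == "continuous":
        if len(groups) == 2:
            res = sps.mannwhitneyu(
                groups[0], groups[1], alternative="two-sided",
                use_continuity=False, method="asymptotic",
            )
            return float(res.pvalue)
        return float(sps.kruskal(*groups).pvalue)
    raise ValueError("kind must be 'categorical' or 'continuous'")
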