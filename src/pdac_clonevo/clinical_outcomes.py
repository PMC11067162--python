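"""Survival machinery and the basal-like-proportion cutoff scan.

Implements the product-limit (Kaplan-Meier) estimator, the two-group
log-rank test (observed-minus-expected with hypergeometric variance), Cox
proportional hazards by Newton-Raphson on the Breslow partial likelihood,
the cutoff-scan procedure that finds the lowest basal-like proportion
threshold splitting patients into prognostic groups, and treatment-response
association tests (RECIST best percent change vs basal-like fraction).

The survival primitives are written out explicitly (rather than wrapped from
a survival library) because downstream tests pin their per-step behaviour:
the log-rank risk table, single Newton steps of the Cox solver and the exact
tie-handling rule are all part of the contract. lifelines serves as an
independent cross-check in the test suite.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, pearsonr

from .clonal_dynamics import wilcoxon_rank_sum

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def km_estimator(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a DataFrame with one row per distinct event time: ``time``,
    ``n_at_risk``, ``n_events``, ``survival``. With censored-only data the
    estimate is S(t) = 1 throughout (empty event table).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValueError("times must be non-negative")
    if len(times) != len(events):
        raise ValueError("times and events must have equal length")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    rows = []
    s = 1.0
    n = len(times)
    for t in np.unique(times[events == 1]):
        at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d / at_risk
        rows.append(dict(time=float(t), n_at_risk=at_risk, n_events=d, survival=s))
    return pd.DataFrame(rows, columns=["time", "n_at_risk", "n_events", "survival"])


def median_survival(times, events) -> float:
    """Smallest event time with KM survival <= 0.5 (inf if never reached)."""
    km = km_estimator(times, events)
    hit = km[km["survival"] <= 0.5]
    return float(hit["time"].iloc[0]) if len(hit) else math.inf


# ---------------------------------------------------------------------------
# log-rank test
# ---------------------------------------------------------------------------

@dataclass
class LogrankResult:
    statistic: float  # chi-square, 1 df
    p: float
    observed_a: float
    expected_a: float
    degenerate: bool = False


def logrank_test(times, events, group) -> LogrankResult:
    """Two-group log-rank test.

    Observed-minus-expected events in group A with the hypergeometric
    variance at each distinct event time; two-sided p from chi-square(1).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError(f"logrank_test needs exactly two groups, got {labels}")
    in_a = group == labels[0]
    o_a = 0.0
    e_a = 0.0
    v = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n_a = int((at_risk & in_a).sum())
        d = int(((times == t) & (events == 1)).sum())
        d_a = int(((times == t) & (events == 1) & in_a).sum())
        o_a += d_a
        e_a += d * n_a / n
        if n > 1:
            v += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    if v == 0:
        logger.info("log-rank variance is zero (no comparable events); p = 1")
        return LogrankResult(statistic=0.0, p=1.0, observed_a=o_a, expected_a=e_a,
                             degenerate=True)
    stat = (o_a - e_a) ** 2 / v
    return LogrankResult(statistic=float(stat), p=float(chi2.sf(stat, df=1)),
                         observed_a=o_a, expected_a=e_a)


# ---------------------------------------------------------------------------
# cutoff scan
# ---------------------------------------------------------------------------

@dataclass
class CutoffScanResult:
    table: pd.DataFrame  # cutoff, n_high, n_low, admissible, statistic, p
    chosen_cutoff: float | None
    alpha: float
    min_group_frac: float


def cutoff_scan(
    proportions,
    times,
    events,
    lo: float = 0.10,
    hi: float = 0.35,
    step: float = 0.01,
    min_group_frac: float = 0.10,
    alpha: float = 0.05,
) -> CutoffScanResult:
    """Scan basal-like-proportion cutoffs for a survival split.

    For each cutoff c in [lo, hi] patients split into fraction > c (high)
    vs <= c (low); a cutoff is admissible iff both groups hold at least
    ``min_group_frac`` of all patients; log-rank is run on admissible
    cutoffs and the chosen cutoff is the lowest admissible one with
    p < alpha (None if there is none — never an exception). The scan is
    fully deterministic.
    """
    proportions = np.asarray(proportions, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(proportions)
    if n < 10:
        raise ValueError("cutoff scan needs at least 10 patients")
    n_steps = int(round((hi - lo) / step))
    cutoffs = np.round(lo + step * np.arange(n_steps + 1), 10)
    min_n = min_group_frac * n
    rows = []
    chosen = None
    for c in cutoffs:
        high = proportions > c
        n_high, n_low = int(high.sum()), int((~high).sum())
        admissible = (n_high >= min_n) and (n_low >= min_n)
        stat = p = np.nan
        if admissible:
            res = logrank_test(times, events, high)
            stat, p = res.statistic, res.p
            if chosen is None and p < alpha:
                chosen = float(c)
        rows.append(dict(cutoff=float(c), n_high=n_high, n_low=n_low,
                         admissible=admissible, statistic=stat, p=p))
    table = pd.DataFrame(rows)
    return CutoffScanResult(table=table, chosen_cutoff=chosen, alpha=alpha,
                            min_group_frac=min_group_frac)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties, Newton-Raphson)
# ---------------------------------------------------------------------------

@dataclass
class CoxResult:
    summary: pd.DataFrame  # coef, hr, se, ci_lower, ci_upper, p per covariate
    loglik: float
    n_iter: int
    converged: bool
    monotone_likelihood_warning: bool = False


def _cox_score_hessian(beta, X, times, events):
    """Breslow partial log-likelihood, score and information at ``beta``.

    Uses suffix sums over times sorted ascending, so tied event times share
    one denominator (Breslow)."""
    order = np.argsort(times, kind="stable")
    Xs = X[order]
    ts = times[order]
    es = events[order]
    eta = Xs @ beta
    w = np.exp(eta)
    # suffix (risk-set) sums
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * Xs)[::-1], axis=0)[::-1]
    s2 = np.cumsum((w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]))[::-1], axis=0)[::-1]
    ll = 0.0
    U = np.zeros(X.shape[1])
    I = np.zeros((X.shape[1], X.shape[1]))
    event_times, first_idx = np.unique(ts[es == 1], return_index=True)
    for t in event_times:
        i = np.searchsorted(ts, t, side="left")
        at = (ts == t) & (es == 1)
        d = int(at.sum())
        xsum = Xs[at].sum(axis=0)
        mean = s1[i] / s0[i]
        ll += xsum @ beta - d * math.log(s0[i])
        U += xsum - d * mean
        I += d * (s2[i] / s0[i] - np.outer(mean, mean))
    return ll, U, I


def cox_ph(
    data: pd.DataFrame,
    covariates,
    time_col: str = "os_months",
    event_col: str = "event",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> CoxResult:
    """Multivariate Cox proportional-hazards fit.

    Newton-Raphson maximization of the Breslow partial likelihood from
    beta = 0, with step-halving; converged when max |delta beta| < tol.
    Per-covariate hazard ratios with 95% CI = exp(beta +- 1.96 SE) and Wald
    p-values. Constant covariates raise an error naming them; apparent
    separation / non-convergence sets a monotone-likelihood warning flag.
    """
    covariates = list(covariates)
    X = data[covariates].to_numpy(dtype=float)
    times = data[time_col].to_numpy(dtype=float)
    events = data[event_col].to_numpy(dtype=int)
    if (times <= 0).any():
        raise ValueError("times must be positive")
    for j, c in enumerate(covariates):
        if np.all(X[:, j] == X[0, j]):
            raise ValueError(f"covariate {c!r} is constant across patients")
    if events.sum() < len(covariates):
        raise ValueError("fewer events than covariates")
    beta = np.zeros(len(covariates))
    ll, U, I = _cox_score_hessian(beta, X, times, events)
    converged = False
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        try:
            delta = np.linalg.solve(I, U)
        except np.linalg.LinAlgError:
            break
        step = 1.0
        for _ in range(30):  # step-halving keeps the likelihood increasing
            new_beta = beta + step * delta
            new_ll, new_U, new_I = _cox_score_hessian(new_beta, X, times, events)
            if new_ll >= ll - 1e-12:
                break
            step /= 2
        beta, ll, U, I = new_beta, new_ll, new_U, new_I
        if np.max(np.abs(step * delta)) < tol:
            converged = True
            break
    warning = (not converged and max_iter > 5) or bool(np.max(np.abs(beta)) > 50)
    if warning:
        logger.warning("Cox fit did not converge cleanly (possible monotone likelihood)")
    try:
        cov = np.linalg.inv(I)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(len(covariates), np.nan)
    z = np.divide(beta, se, out=np.full_like(beta, np.nan), where=se > 0)
    summary = pd.DataFrame(
        dict(
            coef=beta,
            hr=np.exp(beta),
            se=se,
            ci_lower=np.exp(beta - 1.96 * se),
            ci_upper=np.exp(beta + 1.96 * se),
            p=2 * norm.sf(np.abs(z)),
        ),
        index=covariates,
    )
    return CoxResult(summary=summary, loglik=float(ll), n_iter=n_iter,
                     converged=converged, monotone_likelihood_warning=warning)


# ---------------------------------------------------------------------------
# treatment response
# ---------------------------------------------------------------------------

@dataclass
class ResponseAssociation:
    mean_change_high: float  # mean RECIST best % change, fraction > cutoff
    mean_change_low: float
    ranksum_p: float
    r: float
    r_p: float
    n_high: int
    n_low: int
    undefined: bool = False


def response_association(
    basal_fraction,
    recist_pct_change,
    cutoff: float = 0.22,
) -> ResponseAssociation:
    """Associate basal-like fraction with RECIST best percent change.

    Group means for fraction > cutoff vs <= cutoff, a two-sided rank-sum
    test between the groups (needs >= 3 patients per group) and the Pearson
    correlation of fraction vs percent change. Constant percent change gives
    an undefined (flagged) correlation."""
    bf = pd.Series(basal_fraction).astype(float)
    rc = pd.Series(recist_pct_change).reindex(bf.index).astype(float)
    ok = bf.notna() & rc.notna()
    bf, rc = bf[ok], rc[ok]
    high = bf > cutoff
    mean_high = float(rc[high].mean()) if high.any() else np.nan
    mean_low = float(rc[~high].mean()) if (~high).any() else np.nan
    ranksum_p = np.nan
    if high.sum() >= 3 and (~high).sum() >= 3:
        ranksum_p = wilcoxon_rank_sum(rc[high].to_numpy(), rc[~high].to_numpy()).p
    else:
        logger.warning("fewer than 3 patients in a RECIST group; rank-sum skipped")
    undefined = False
    if rc.nunique() <= 1 or bf.nunique() <= 1:
        logger.warning("constant input; RECIST correlation undefined")
        r = r_p = np.nan
        undefined = True
    else:
        r, r_p = pearsonr(bf, rc)
    return ResponseAssociation(
        mean_change_high=mean_high, mean_change_low=mean_low,
        ranksum_p=float(ranksum_p) if ranksum_p == ranksum_p else np.nan,
        r=float(r) if r == r else np.nan, r_p=float(r_p) if r_p == r_p else np.nan,
        n_high=int(high.sum()), n_low=int((~high).sum()), undefined=undefined,
    )
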