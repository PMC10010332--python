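"""Exact and survival statistics used across the pipeline.

Self-contained implementations of the two-sided Fisher exact test
(exhaustive hypergeometric enumeration in log space), the Kaplan–Meier
product-limit estimator, and the k-sample log-rank test.  These are the
statistical primitives the reporting modules depend on; the test suite
cross-checks them against independent references.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "fisher_exact",
    "KaplanMeierFit",
    "km_estimate",
    "LogrankResult",
    "logrank_test",
]

# Relative tolerance when deciding whether an alternative table is "as
# extreme" as the observed one: float rounding must not drop exact ties.
_FISHER_REL_EPS = 1e-7


def _log_binom(n: float, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 contingency table.

    With margins fixed, sums the hypergeometric probability of every
    table whose probability is less than or equal to the observed
    table's (within relative tolerance 1e-7, so exact ties are kept
    despite log-space rounding).  Computation is in log space and never
    overflows.  A table with an empty row or column margin has a single
    attainable configuration and returns p = 1 (with a warning).
    """
    a, b = table[0]
    c, d = table[1]
    if min(a, b, c, d) < 0 or any(
        int(x) != x for x in (a, b, c, d)
    ):
        raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        warnings.warn("empty margin in 2x2 table; p = 1")
        return 1.0
    k = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    logp = _log_binom(r1, k) + _log_binom(r2, c1 - k) - _log_binom(n, np.array([c1]))
    log_obs = logp[k == a][0]
    keep = logp <= log_obs + np.log1p(_FISHER_REL_EPS)
    # log-sum-exp over the qualifying tables
    m = logp[keep].max()
    p = float(np.exp(m) * np.exp(logp[keep] - m).sum())
    return min(p, 1.0)


@dataclass
class KaplanMeierFit:
    """Product-limit survival estimate.

    ``times`` are the distinct event times in increasing order,
    ``survival`` the estimate just after each, ``at_risk``/``n_events``
    the risk-set size and event count at each.  ``S(0) = 1``.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    median: float  # NaN when the curve never reaches 0.5

    def survival_at(self, t: float) -> float:
        """S(t): probability of surviving beyond time t."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KaplanMeierFit:
    """Kaplan–Meier product-limit estimator.

    ``events`` is 1 for an observed event, 0 for right-censoring.  With
    no censoring the estimate equals the empirical survivor function.
    The median is the smallest event time with S(t) <= 0.5 (NaN if never
    reached).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("no observations")
    if (times < 0).any():
        raise ValueError("negative times")
    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]

    event_times = np.unique(times[events == 1])
    n = times.size
    surv, at_risk_l, d_l = [], [], []
    s = 1.0
    for t in event_times:
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / at_risk
        surv.append(s)
        at_risk_l.append(at_risk)
        d_l.append(d)
    surv_arr = np.array(surv)
    below = np.nonzero(surv_arr <= 0.5)[0] if surv_arr.size else np.array([])
    median = float(event_times[below[0]]) if below.size else float("nan")
    return KaplanMeierFit(
        times=event_times,
        survival=surv_arr,
        at_risk=np.array(at_risk_l),
        n_events=np.array(d_l),
        median=median,
    )


@dataclass
class LogrankResult:
    statistic: float
    p_value: float
    df: int
    observed: np.ndarray
    expected: np.ndarray


def logrank_test(groups, times, events) -> LogrankResult:
    """k-sample log-rank test over pooled event times.

    Compares observed vs expected events per group under the null of a
    common hazard, with the usual hypergeometric variance; the statistic
    is chi-squared with k-1 degrees of freedom.  Identical groups give a
    statistic of 0 and p = 1.
    """
    from scipy.stats import chi2

    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    labels = np.unique(groups)
    k = labels.size
    if k < 2:
        raise ValueError("need at least two groups")
    for lab in labels:
        if (groups == lab).sum() == 0:
            raise ValueError(f"group {lab} has no subjects")

    g_idx = np.searchsorted(labels, groups)
    event_times = np.unique(times[events == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    # covariance of the first k-1 group event counts, summed over times
    V = np.zeros((k - 1, k - 1))
    for t in event_times:
        at_risk_mask = times >= t
        n_t = at_risk_mask.sum()
        d_t = int(((times == t) & (events == 1)).sum())
        n_g = np.bincount(g_idx[at_risk_mask], minlength=k).astype(float)
        d_g = np.bincount(
            g_idx[(times == t) & (events == 1)], minlength=k
        ).astype(float)
        O += d_g
        E += d_t * n_g / n_t
        if n_t > 1:
            frac = n_g / n_t
            mult = d_t * (n_t - d_t) / (n_t - 1)
            cov = mult * (np.diag(frac) - np.outer(frac, frac))
            V += cov[: k - 1, : k - 1]
    z = (O - E)[: k - 1]
    if not np.any(np.abs(z) > 0) or np.allclose(V, 0):
        stat = 0.0
    else:
        stat = float(z @ np.linalg.pinv(V) @ z)
    p = float(chi2.sf(stat, k - 1)) if stat > 0 else 1.0
    return LogrankResult(
        statistic=stat, p_value=p, df=k - 1, observed=O, expected=E
    )
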