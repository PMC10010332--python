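"""Fisher exact, Kaplan-Meier and log-rank implementations."""

from math import comb

import numpy as np
import pytest

from lesionscope.stats import fisher_exact, km_estimate, logrank_test


def fisher_oracle(a, b, c, d):
    """Exact-rational two-sided Fisher p by integer enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    obs = comb(r1, a) * comb(r2, c1 - a)
    num = sum(
        w
        for k in range(max(0, c1 - r2), min(r1, c1) + 1)
        if (w := comb(r1, k) * comb(r2, c1 - k)) <= obs
    )
    return num / comb(n, c1)


def test_fisher_two_tables_each_half():
    assert fisher_exact(((1, 0), (0, 1))) == pytest.approx(1.0)


def test_fisher_extreme_diagonal():
    assert fisher_exact(((5, 0), (0, 5))) == pytest.approx(2 / 252, rel=1e-9)


def test_fisher_empty_margin_warns_p1():
    with pytest.warns(UserWarning):
        assert fisher_exact(((0, 5), (0, 7))) == 1.0


def test_fisher_rejects_bad_input():
    with pytest.raises(ValueError):
        fisher_exact(((-1, 2), (3, 4)))
    with pytest.raises(ValueError):
        fisher_exact(((1.5, 2), (3, 4)))


def test_fisher_transpose_and_row_swap_invariance(rng):
    for _ in range(50):
        a, b, c, d = (int(x) for x in rng.integers(0, 30, size=4))
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            continue
        p = fisher_exact(((a, b), (c, d)))
        assert fisher_exact(((a, c), (b, d))) == pytest.approx(p, rel=1e-9)
        assert fisher_exact(((c, d), (a, b))) == pytest.approx(p, rel=1e-9)


def test_fisher_matches_enumeration_on_random_tables(rng):
    for _ in range(200):
        a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            continue
        assert fisher_exact(((a, b), (c, d))) == pytest.approx(
            fisher_oracle(a, b, c, d), rel=1e-7
        )


def test_fisher_matches_scipy(rng):
    from scipy.stats import fisher_exact as scipy_fisher

    for _ in range(100):
        a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            continue
        assert fisher_exact(((a, b), (c, d))) == pytest.approx(
            scipy_fisher([[a, b], [c, d]])[1], rel=1e-6
        )


def test_fisher_large_counts_no_overflow():
    p = fisher_exact(((900, 100), (100, 900)))
    assert 0 <= p < 1e-100 or 0 <= p <= 1  # finite, no overflow
    assert np.isfinite(p)


def test_km_no_censoring_is_empirical():
    fit = km_estimate([1, 2, 3], [1, 1, 1])
    assert fit.survival_at(0) == 1.0
    assert fit.survival_at(1) == pytest.approx(2 / 3)
    assert fit.survival_at(2) == pytest.approx(1 / 3)
    assert fit.survival_at(3) == 0.0


def test_km_all_censored_stays_at_one():
    fit = km_estimate([5, 8, 13], [0, 0, 0])
    assert fit.survival_at(100) == 1.0
    assert np.isnan(fit.median)


def test_km_hand_worked_product_limit():
    """n=6 with interleaved censoring, against the hand-computed table.

    times (1,2,3,4,5,6), events (1,0,1,1,0,1):
    S(1)=5/6, S(3)=5/6*3/4=5/8, S(4)=5/8*2/3=5/12, S(6)=0.
    """
    fit = km_estimate([1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1])
    np.testing.assert_allclose(fit.times, [1, 3, 4, 6])
    np.testing.assert_allclose(fit.survival, [5 / 6, 5 / 8, 5 / 12, 0.0])
    assert fit.median == 4.0  # first event time with S <= 0.5


def test_km_ties_handled():
    fit = km_estimate([2, 2, 2, 5], [1, 1, 0, 1])
    # t=2: 3 at risk minus... 4 at risk, 2 events -> S = 1/2
    assert fit.survival_at(2) == pytest.approx(0.5)


def test_km_matches_lifelines(rng):
    from lifelines import KaplanMeierFitter

    t = rng.exponential(100, size=80)
    c = rng.exponential(120, size=80)
    times = np.minimum(t, c)
    events = (t <= c).astype(int)
    fit = km_estimate(times, events)
    kmf = KaplanMeierFitter().fit(times, events)
    for q in np.quantile(times, [0.1, 0.3, 0.5, 0.7, 0.9]):
        assert fit.survival_at(q) == pytest.approx(
            float(kmf.predict(q)), abs=1e-9
        )


def test_km_empty_raises():
    with pytest.raises(ValueError):
        km_estimate([], [])


def test_logrank_identical_groups_p1():
    times = [3, 5, 8, 13, 21]
    events = [1, 1, 0, 1, 1]
    res = logrank_test(
        ["a"] * 5 + ["b"] * 5, times + times, events + events
    )
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == 1.0


def test_logrank_matches_lifelines_two_groups(rng):
    from lifelines.statistics import logrank_test as ll_logrank

    n = 60
    t1, t2 = rng.exponential(100, n), rng.exponential(60, n)
    c = rng.exponential(200, 2 * n)
    times = np.concatenate([t1, t2])
    events = (times <= c).astype(int)
    times = np.minimum(times, c)
    groups = ["a"] * n + ["b"] * n
    res = logrank_test(groups, times, events)
    ll = ll_logrank(
        times[:n], times[n:], event_observed_A=events[:n],
        event_observed_B=events[n:],
    )
    assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-6)
    assert res.p_value == pytest.approx(ll.p_value, rel=1e-6)


def test_logrank_matches_lifelines_three_groups(rng):
    from lifelines.statistics import multivariate_logrank_test

    import pandas as pd

    n = 40
    times = np.concatenate(
        [rng.exponential(s, n) for s in (100, 60, 30)]
    )
    events = np.ones_like(times, dtype=int)
    groups = np.repeat(["a", "b", "c"], n)
    res = logrank_test(groups, times, events)
    df = pd.DataFrame({"t": times, "e": events, "g": groups})
    ll = multivariate_logrank_test(df["t"], df["g"], df["e"])
    assert res.df == 2
    assert res.statistic == pytest.approx(ll.test_statistic, rel=1e-6)


def test_logrank_detects_hazard_ratio():
    """Exponential survival with hazard ratio 3, n=200/arm: tiny p."""
    hits = 0
    for rep in range(20):
        r = np.random.default_rng(1000 + rep)
        t1, t2 = r.exponential(90, 200), r.exponential(30, 200)
        res = logrank_test(
            ["a"] * 200 + ["b"] * 200,
            np.concatenate([t1, t2]),
            np.ones(400, dtype=int),
        )
        hits += res.p_value < 0.001
    assert hits >= 19


def test_logrank_permutation_null_is_uniform(rng):
    """Permuted labels on one sample give approximately uniform p."""
    from scipy.stats import kstest

    times = rng.exponential(50, size=60)
    events = (rng.random(60) < 0.8).astype(int)
    pvals = []
    for _ in range(500):
        labels = rng.permutation(["a"] * 30 + ["b"] * 30)
        pvals.append(logrank_test(labels, times, events).p_value)
    assert kstest(pvals, "uniform").pvalue > 0.01


def test_logrank_requires_two_nonempty_groups():
    with pytest.raises(ValueError):
        logrank_test(["a", "a"], [1, 2], [1, 1])
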