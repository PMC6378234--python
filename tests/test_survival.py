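"""Unit and property tests for the censored-data primitives, cross-checked
against hand computations and the independent lifelines implementation."""

import numpy as np
import pytest
from scipy import stats

from lncrisk import cox_fit, km_estimate, logrank_test, t_test
from lncrisk.survival import cox_partial_loglik


# ---------------------------------------------------------------- Kaplan-Meier

def test_km_no_censoring_is_one_minus_ecdf():
    km = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
    assert np.allclose(km.surv, [0.75, 0.5, 0.25, 0.0])
    rng = np.random.default_rng(0)
    t = rng.exponential(1, 50)
    km = km_estimate(t, np.ones(50))
    ecdf = np.array([(t <= x).mean() for x in km.times])
    assert np.allclose(km.surv, 1 - ecdf)


def test_km_censoring_fixture():
    km = km_estimate([1, 2, 3], [1, 0, 1])
    assert np.allclose(km.times, [1, 3])
    assert np.allclose(km.surv, [2 / 3, 0.0])
    assert km.survival_at(2) == pytest.approx(2 / 3)
    assert km.median_survival == 3.0


def test_km_all_censored_flat_curve_no_median():
    km = km_estimate([1, 2, 3], [0, 0, 0])
    assert km.times.size == 0
    assert km.survival_at(10) == 1.0
    assert km.median_survival is None


def test_km_rejects_empty_and_nonpositive():
    with pytest.raises(ValueError):
        km_estimate([], [])
    with pytest.raises(ValueError):
        km_estimate([0.0, 1.0], [1, 1])


def test_km_matches_lifelines():
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(4)
    t = rng.exponential(1, 80).round(2) + 0.01
    e = (rng.uniform(size=80) < 0.6).astype(int)
    km = km_estimate(t, e)
    kmf = lifelines.KaplanMeierFitter().fit(t, e)
    ours = [km.survival_at(x) for x in km.times]
    theirs = [float(kmf.predict(x)) for x in km.times]
    assert np.allclose(ours, theirs)


# ------------------------------------------------------------------- log-rank

def test_logrank_hand_computed_fixture():
    # O-E = 7/6 and V = 17/36 for A=(1,2) vs B=(3,4), all events
    res = logrank_test([1, 2, 3, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])
    assert res.chi2 == pytest.approx(49 / 17)
    assert res.p == pytest.approx(stats.chi2.sf(49 / 17, 1))
    assert res.observed[0] == 2
    assert res.expected[0] == pytest.approx(5 / 6)


def test_logrank_label_symmetry():
    t = [1, 2, 3, 4, 5, 6]
    e = [1, 0, 1, 1, 0, 1]
    g1 = ["A", "A", "A", "B", "B", "B"]
    g2 = ["B", "B", "B", "A", "A", "A"]
    a = logrank_test(t, e, g1)
    b = logrank_test(t, e, g2)
    assert a.chi2 == pytest.approx(b.chi2)
    assert a.p == pytest.approx(b.p)


def test_logrank_identical_groups_null():
    t = [1, 2, 3, 1, 2, 3]
    e = [1, 0, 1, 1, 0, 1]
    res = logrank_test(t, e, ["A"] * 3 + ["B"] * 3)
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def test_logrank_requires_two_groups():
    with pytest.raises(ValueError):
        logrank_test([1, 2], [1, 1], ["A", "A"])


def test_logrank_three_groups_matches_lifelines():
    lifelines = pytest.importorskip("lifelines")
    from lifelines.statistics import multivariate_logrank_test

    rng = np.random.default_rng(9)
    t = rng.exponential(1, 90)
    e = (rng.uniform(size=90) < 0.7).astype(int)
    g = rng.choice(["a", "b", "c"], 90)
    ours = logrank_test(t, e, g)
    theirs = multivariate_logrank_test(t, g, e)
    assert ours.df == 2
    assert ours.chi2 == pytest.approx(theirs.test_statistic, rel=1e-6)


# ------------------------------------------------------------------------ Cox

def _hand_efron_loglik(beta, time, event, x):
    """Independent re-derivation of the Efron partial log-likelihood."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        D = np.nonzero((time == t) & (event == 1))[0]
        R = np.nonzero(time >= t)[0]
        d = len(D)
        ll += beta * x[D].sum()
        sR = np.exp(beta * x[R]).sum()
        sD = np.exp(beta * x[D]).sum()
        for l in range(d):
            ll -= np.log(sR - l / d * sD)
    return ll


def test_cox_matches_hand_written_likelihood_grid():
    t = [1.0, 3.0, 2.0, 4.0]
    e = [1, 1, 1, 1]
    x = [1.0, 1.0, 0.0, 0.0]
    grid = np.linspace(-2, 4, 60001)
    ll = [_hand_efron_loglik(b, t, e, x) for b in grid]
    b_star = grid[int(np.argmax(ll))]
    fit = cox_fit(t, e, x)
    assert abs(fit.beta[0] - b_star) < 1e-3
    assert fit.beta[0] == pytest.approx(0.9406, abs=1e-3)
    assert fit.hr[0] == pytest.approx(np.exp(fit.beta[0]))
    assert fit.ci_low[0] < fit.hr[0] < fit.ci_high[0]


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_cox_grid_oracle_on_small_fixtures(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(4, 9)
    t = rng.exponential(1, n) + 0.05
    e = np.ones(n, int)
    x = rng.standard_normal(n)
    grid = np.linspace(-6, 6, 120001)
    ll = [cox_partial_loglik([b], t, e, x) for b in grid[::200]]
    coarse = grid[::200][int(np.argmax(ll))]
    fine = np.linspace(coarse - 0.2, coarse + 0.2, 40001)
    llf = [cox_partial_loglik([b], t, e, x) for b in fine]
    b_star = fine[int(np.argmax(llf))]
    fit = cox_fit(t, e, x)
    if abs(b_star) < 5.5:  # interior maximum, not separation
        assert abs(fit.beta[0] - b_star) < 1e-3


def test_cox_depends_only_on_time_ranks():
    rng = np.random.default_rng(1)
    t = rng.exponential(1, 40)
    e = (rng.uniform(size=40) < 0.7).astype(int)
    x = rng.standard_normal(40)
    a = cox_fit(t, e, x)
    ranks = stats.rankdata(t, method="ordinal").astype(float)
    b = cox_fit(ranks, e, x)
    assert a.beta[0] == pytest.approx(b.beta[0], abs=1e-8)


def test_cox_degenerate_inputs():
    with pytest.raises(ValueError, match="constant"):
        cox_fit([1, 2, 3], [1, 1, 0], [0.0, 0.0, 0.0])
    with pytest.raises(ValueError, match="event"):
        cox_fit([1, 2, 3], [0, 0, 0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="finite"):
        cox_fit([1, 2, 3], [1, 1, 0], [1.0, np.nan, 3.0])


def test_cox_flags_separation():
    # perfectly separated: all x=1 die first
    t = [1, 2, 3, 10, 11, 12]
    e = [1, 1, 1, 1, 1, 1]
    x = [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]
    fit = cox_fit(t, e, x)
    assert fit.separation


@pytest.mark.parametrize("ties", ["efron", "breslow"])
def test_cox_matches_lifelines(ties):
    lifelines = pytest.importorskip("lifelines")
    import pandas as pd

    rng = np.random.default_rng(7)
    n = 120
    X = rng.standard_normal((n, 2))
    t = rng.exponential(np.exp(-(0.5 * X[:, 0] - 0.3 * X[:, 1])))
    c = rng.exponential(1.5, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    if ties == "breslow":
        time = time.round(1) + 0.05  # force ties
    ours = cox_fit(time, event, X, ties=ties)
    df = pd.DataFrame({"t": time, "e": event, "x0": X[:, 0], "x1": X[:, 1]})
    cph = lifelines.CoxPHFitter()
    cph.fit(df, "t", "e")  # lifelines default tie handling is Efron
    if ties == "efron":
        assert np.allclose(ours.beta, cph.params_.to_numpy(), atol=1e-5)
        assert np.allclose(ours.se, cph.standard_errors_.to_numpy(), atol=1e-5)
    else:
        assert np.allclose(ours.beta, cph.params_.to_numpy(), atol=0.05)


def test_cox_wald_agrees_with_logrank_on_binary_covariate():
    rng = np.random.default_rng(21)
    n = 400
    x = (rng.uniform(size=n) < 0.5).astype(float)
    t = rng.exponential(np.exp(-0.5 * x))
    c = rng.exponential(2.0, n)
    time = np.minimum(t, c)
    event = (t <= c).astype(int)
    fit = cox_fit(time, event, x)
    wald_chi2 = (fit.beta[0] / fit.se[0]) ** 2
    lr = logrank_test(time, event, np.where(x > 0, "hi", "lo"))
    assert abs(wald_chi2 - lr.chi2) / lr.chi2 < 0.15


def test_cox_null_pvalues_uniform():
    """Under exponential survival independent of the covariate, Wald
    p-values are uniform (KS distance < 0.05 over 2000 refits)."""
    rng = np.random.default_rng(100)
    n = 150
    ps = np.empty(2000)
    for i in range(2000):
        time = rng.exponential(1.0, n)
        c = rng.exponential(1.2, n)
        obs = np.minimum(time, c)
        event = (time <= c).astype(int)
        x = rng.standard_normal(n)
        ps[i] = cox_fit(obs, event, x).p[0]
    ks = stats.kstest(ps, "uniform").statistic
    assert ks < 0.05


# --------------------------------------------------------------------- t-test

def test_t_test_hand_fixture_and_symmetries():
    x, y = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
    t, p = t_test(x, y)
    assert t == pytest.approx(-3.0 / np.sqrt(2 / 3))
    assert abs(t) == pytest.approx(3.674, abs=1e-3)
    assert p == pytest.approx(0.0214, abs=1e-3)
    t2, p2 = t_test(y, x)
    assert t2 == pytest.approx(-t)
    assert p2 == pytest.approx(p)
    assert t_test(x, x) == (0.0, 1.0)


def test_t_test_zero_variance_unequal_means_errors():
    with pytest.raises(ValueError):
        t_test([1.0, 1.0], [2.0, 2.0])


def test_t_test_matches_scipy():
    rng = np.random.default_rng(2)
    x = rng.normal(0, 1, 20)
    y = rng.normal(0.5, 1, 15)
    t, p = t_test(x, y)
    ref = stats.ttest_ind(x, y)
    assert t == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue)
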