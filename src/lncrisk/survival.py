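"""Self-contained statistics for right-censored survival data.

Implements the product-limit (Kaplan-Meier) estimator, the Mantel-Cox
log-rank test, Cox proportional-hazards regression (Newton-Raphson on the
partial likelihood, Efron or Breslow tie handling) and the pooled-variance
two-sample t-test.  These primitives back every downstream stage of the
risk-score pipeline, so they are written directly against the textbook
formulas rather than wrapping an external survival library; external
libraries serve only as cross-checks in the test suite.

Conventions
-----------
* ``time`` is strictly positive; units (days/months) are the caller's.
* ``event`` is 1 if the event was observed, 0 if censored.
* Samples censored exactly at an event time are counted as at risk at that
  time (the standard convention).
* Confidence intervals are 95% Wald intervals on the log-hazard scale.
"""

from __future__ import annotations

import math as _math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as _stats

__all__ = [
    "KMCurve",
    "LogRankResult",
    "CoxResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "t_test",
]

#: Newton-Raphson stops when the largest score component falls below this.
SCORE_TOL = 1e-8
#: Maximum Newton iterations before giving up.
MAX_ITER = 50
#: |beta| beyond this is flagged as monotone-likelihood (separation).
SEPARATION_BOUND = 15.0


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit survival curve.

    ``times`` are the distinct observed *event* times (increasing); ``surv``
    the estimated survival probability just after each, with ``at_risk`` and
    ``deaths`` the risk-set size and event count at each time.
    ``median_survival`` is the first event time at which survival drops to
    <= 0.5, or ``None`` if the curve never reaches 0.5.
    """

    times: np.ndarray
    surv: np.ndarray
    at_risk: np.ndarray
    deaths: np.ndarray
    median_survival: float | None
    n: int

    def survival_at(self, t: float) -> float:
        """Step-function evaluation S(t) (right-continuous)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.surv[idx])

    def survival_before(self, t: float) -> float:
        """Left limit S(t-), i.e. survival just before ``t``."""
        idx = np.searchsorted(self.times, t, side="left") - 1
        return 1.0 if idx < 0 else float(self.surv[idx])


def _validate_time_event(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.ndim != 1 or time.size == 0:
        raise ValueError("time must be a non-empty 1-D array")
    if time.shape != event.shape:
        raise ValueError("time and event must have the same length")
    if not np.all(np.isfinite(time)) or np.any(time <= 0):
        raise ValueError("survival times must be finite and > 0")
    ev = event.astype(float)
    if not np.all(np.isin(ev, (0.0, 1.0))):
        raise ValueError("event indicator must be 0 (censored) or 1 (event)")
    return time, ev.astype(int)


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    With no censoring this reduces to 1 minus the empirical CDF evaluated at
    the event times.  The median is the first event time where the curve
    reaches 0.5 or below, and is ``None`` when the curve never gets there
    (e.g. everything censored).
    """
    time, event = _validate_time_event(time, event)
    n = time.size
    event_times = np.unique(time[event == 1])
    if event_times.size == 0:
        return KMCurve(
            times=np.empty(0),
            surv=np.empty(0),
            at_risk=np.empty(0, dtype=int),
            deaths=np.empty(0, dtype=int),
            median_survival=None,
            n=n,
        )
    # at risk at t: everyone with observed time >= t (ties included)
    at_risk = np.array([(time >= t).sum() for t in event_times])
    deaths = np.array([((time == t) & (event == 1)).sum() for t in event_times])
    # exact rational cumulative product (numerator/denominator in Python
    # ints), so e.g. the no-censoring curve equals 1 - ECDF to the bit
    num, den = 1, 1
    surv = np.empty(event_times.size)
    for i, (n_i, d_i) in enumerate(zip(at_risk.tolist(), deaths.tolist())):
        num *= n_i - d_i
        den *= n_i
        if num == 0:
            surv[i:] = 0.0
            break
        g = _math.gcd(num, den)
        num //= g
        den //= g
        surv[i] = num / den
    below = np.nonzero(surv <= 0.5)[0]
    median = float(event_times[below[0]]) if below.size else None
    return KMCurve(event_times, surv, at_risk, deaths, median, n)


# ---------------------------------------------------------------------------
# Log-rank test
# ---------------------------------------------------------------------------


@dataclass
class LogRankResult:
    """Mantel-Cox log-rank test over k groups (df = k - 1)."""

    chi2: float
    p: float
    df: int
    observed: np.ndarray  # events per group
    expected: np.ndarray  # expected events per group under H0
    groups: list


def logrank_test(time, event, group) -> LogRankResult:
    """Mantel-Cox log-rank test of equality of survival curves.

    At each distinct event time the observed event count per group is
    compared with its hypergeometric expectation given the risk sets; the
    two-group statistic is (sum O - sum E)^2 / sum V with the hypergeometric
    variance, and the k-group statistic is the quadratic form over the first
    k-1 groups.  P-value from the chi-square distribution with k-1 df.
    """
    time, event = _validate_time_event(time, event)
    group = np.asarray(group)
    if group.shape != time.shape:
        raise ValueError("group labels must match time in length")
    labels, ginv = np.unique(group, return_inverse=True)
    k = labels.size
    if k < 2:
        raise ValueError("log-rank test requires at least two groups")

    event_times = np.unique(time[event == 1])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = time >= t
        n_t = at_risk.sum()
        d_t = ((time == t) & (event == 1)).sum()
        n_g = np.bincount(ginv[at_risk], minlength=k).astype(float)
        d_g = np.bincount(ginv[(time == t) & (event == 1)], minlength=k).astype(float)
        O += d_g
        E += d_t * n_g / n_t
        if n_t > 1:
            frac = n_g / n_t
            # hypergeometric covariance of events per group at this time
            V += (
                d_t
                * (n_t - d_t)
                / (n_t - 1)
                * (np.diag(frac) - np.outer(frac, frac))
            )
    z = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    if z.size == 1:
        chi2 = float(z[0] ** 2 / Vsub[0, 0]) if Vsub[0, 0] > 0 else 0.0
    else:
        chi2 = float(z @ np.linalg.pinv(Vsub) @ z)
    chi2 = max(chi2, 0.0)
    p = float(_stats.chi2.sf(chi2, k - 1))
    return LogRankResult(chi2, p, k - 1, O, E, list(labels))


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


@dataclass
class CoxResult:
    """Cox PH fit: per-covariate log-hazard ratios and Wald inference."""

    names: list
    beta: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    loglik: float
    n: int
    n_events: int
    converged: bool
    separation: bool
    n_iter: int = 0

    def summary_row(self, j: int = 0) -> dict:
        return {
            "name": self.names[j],
            "beta": float(self.beta[j]),
            "se": float(self.se[j]),
            "hr": float(self.hr[j]),
            "ci_low": float(self.ci_low[j]),
            "ci_high": float(self.ci_high[j]),
            "p": float(self.p[j]),
        }


def cox_partial_loglik(
    beta, time, event, X, ties: str = "efron"
) -> float:
    """Log partial likelihood at ``beta`` (exposed for oracle checks)."""
    time, event = _validate_time_event(time, event)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != time.size:
        X = X.T
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    ll, _, _ = _cox_derivatives(beta, *_cox_prepare(time, event, X), ties=ties)
    return ll


def _cox_prepare(time, event, X):
    order = np.argsort(time, kind="stable")
    return time[order], event[order], X[order]


def _cox_derivatives(beta, time, event, X, ties="efron"):
    """Log partial likelihood, score vector and observed information.

    Data must be sorted by ascending time.  Risk sets are suffixes of the
    sorted arrays; tied event times are handled by the Efron correction
    (each of the d tied events sees the risk-set weight reduced by l/d of
    the tied group's weight) or by Breslow's approximation.
    """
    n, p = X.shape
    eta = X @ beta
    m = eta.max()
    w = np.exp(eta - m)  # shifted to avoid overflow; ratios are unaffected
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    # suffix sums: S[i] = sum_{j >= i}
    S = np.cumsum(w[::-1])[::-1]
    Z = np.cumsum(wx[::-1], axis=0)[::-1]
    Q = np.cumsum(wxx[::-1], axis=0)[::-1]

    if n > 1 and np.unique(time).size == n:
        # all times distinct: every risk set is a plain suffix and the tie
        # corrections vanish, so the sums vectorize over event indices
        ev = np.nonzero(event == 1)[0]
        S_e = S[ev]
        Z_e = Z[ev]
        ll = float(eta[ev].sum()) - ev.size * m - float(np.log(S_e).sum())
        score = X[ev].sum(axis=0) - (Z_e / S_e[:, None]).sum(axis=0)
        zn = Z_e / S_e[:, None]
        info = (Q[ev] / S_e[:, None, None]).sum(axis=0) - np.einsum(
            "ij,ik->jk", zn, zn
        )
        return ll, score, info

    ll = 0.0
    score = np.zeros(p)
    info = np.zeros((p, p))
    i = 0
    while i < n:
        t = time[i]
        j = i
        while j < n and time[j] == t:
            j += 1
        d_idx = np.arange(i, j)[event[i:j] == 1]
        d = d_idx.size
        if d > 0:
            S_R, Z_R, Q_R = S[i], Z[i], Q[i]
            ll += float(eta[d_idx].sum()) - d * m
            score += X[d_idx].sum(axis=0)
            if ties == "efron":
                S_D = w[d_idx].sum()
                Z_D = wx[d_idx].sum(axis=0)
                Q_D = wxx[d_idx].sum(axis=0)
                for l in range(d):
                    f = l / d
                    phi = S_R - f * S_D
                    zl = Z_R - f * Z_D
                    ql = Q_R - f * Q_D
                    ll -= np.log(phi)
                    score -= zl / phi
                    info += ql / phi - np.outer(zl, zl) / phi**2
            elif ties == "breslow":
                for _ in range(d):
                    ll -= np.log(S_R)
                    score -= Z_R / S_R
                    info += Q_R / S_R - np.outer(Z_R, Z_R) / S_R**2
            else:  # pragma: no cover - guarded upstream
                raise ValueError(f"unknown tie method {ties!r}")
        i = j
    return ll, score, info


def cox_fit(time, event, covariates, names: Sequence | None = None,
            ties: str = "efron") -> CoxResult:
    """Fit a Cox proportional-hazards model by Newton-Raphson.

    Parameters
    ----------
    covariates
        (n, p) matrix (a 1-D array is treated as a single covariate).
    ties
        ``"efron"`` (default) or ``"breslow"`` tie handling.

    Maximizes the partial likelihood from beta = 0 with step-halving;
    convergence when the largest score component is below 1e-8 (or 50
    iterations).  Standard errors come from the inverse observed
    information; separation (monotone likelihood) is flagged when any
    |beta| exceeds 15.

    Raises
    ------
    ValueError
        if there are no events, non-finite covariates, or a constant
        (zero-variance) covariate column.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown tie method {ties!r}")
    time, event = _validate_time_event(time, event)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != time.size:
        raise ValueError("covariate rows must match number of samples")
    n, p = X.shape
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite")
    if event.sum() == 0:
        raise ValueError("Cox regression requires at least one event")
    if n <= p:
        raise ValueError("need more samples than covariates")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        j = int(np.nonzero(sd == 0)[0][0])
        nm = names[j] if names is not None else f"x{j}"
        raise ValueError(f"covariate {nm!r} is constant; coefficient undefined")
    if names is None:
        names = [f"x{j}" for j in range(p)]

    center = X.mean(axis=0)
    Xc = X - center  # beta is invariant to centering; conditioning is not
    ts, es, Xs = _cox_prepare(time, event, Xc)

    beta = np.zeros(p)
    ll, score, info = _cox_derivatives(beta, ts, es, Xs, ties=ties)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        if np.max(np.abs(score)) < SCORE_TOL:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # step-halving to guarantee ascent
        new_beta = beta + step
        new_ll, new_score, new_info = _cox_derivatives(new_beta, ts, es, Xs, ties=ties)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 30:
            step *= 0.5
            halvings += 1
            new_beta = beta + step
            new_ll, new_score, new_info = _cox_derivatives(
                new_beta, ts, es, Xs, ties=ties
            )
        beta, ll, score, info = new_beta, new_ll, new_score, new_info
    else:
        it = MAX_ITER
    if not converged and np.max(np.abs(score)) < SCORE_TOL:
        converged = True

    separation = bool(np.any(np.abs(beta) > SEPARATION_BOUND))
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    zcrit = _stats.norm.ppf(0.975)
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        hr = np.exp(beta)
        ci_low = np.exp(beta - zcrit * se)
        ci_high = np.exp(beta + zcrit * se)
        zstat = beta / se
    pvals = 2.0 * _stats.norm.sf(np.abs(zstat))
    return CoxResult(
        names=list(names),
        beta=beta,
        se=se,
        hr=hr,
        ci_low=ci_low,
        ci_high=ci_high,
        p=pvals,
        loglik=float(ll),
        n=n,
        n_events=int(event.sum()),
        converged=converged,
        separation=separation,
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# Student's t
# ---------------------------------------------------------------------------


def t_test(x, y) -> tuple[float, float]:
    """Pooled-variance two-sample Student's t-test (two-sided).

    Returns ``(t, p)`` with ``n_x + n_y - 2`` degrees of freedom.  A zero
    pooled variance with equal means yields (0, 1); with unequal means it is
    an error (infinite statistic).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two observations")
    nx, ny = x.size, y.size
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    df = nx + ny - 2
    sp2 = ((nx - 1) * vx + (ny - 1) * vy) / df
    diff = x.mean() - y.mean()
    if sp2 == 0:
        if diff == 0:
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means")
    t = diff / np.sqrt(sp2 * (1 / nx + 1 / ny))
    p = 2.0 * _stats.t.sf(abs(t), df)
    return float(t), float(p)
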