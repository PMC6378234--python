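"""Time-dependent ROC analysis for censored survival outcomes.

Cumulative/dynamic definition at horizon t: *cases* are samples with an
observed event by t, *controls* are samples still under observation beyond
t.  Two estimators:

* ``exclude_censored`` (default) — samples censored before t carry no
  information about case/control status and are dropped;
* ``ipcw`` — inverse-probability-of-censoring weighting: cases weighted by
  1/G(T-), controls by 1/G(t), with G the Kaplan-Meier estimate of the
  censoring survival function; consistent under independent censoring.

The ROC curve sweeps score thresholds from high to low; AUC is the
trapezoid area over the empirical curve, which gives tied scores half
credit.  The default horizon is the cohort's KM median survival time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CohortBundle
from .survival import km_estimate

__all__ = ["ROCCurve", "td_roc", "compare_signatures", "default_horizon"]


@dataclass
class ROCCurve:
    horizon: float
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    estimator: str
    n_cases: int
    n_controls: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "tpr": self.tpr[1:], "fpr": self.fpr[1:]}
        )

    def summary(self) -> dict:
        return {
            "t": float(self.horizon),
            "auc": float(self.auc),
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "estimator": self.estimator,
        }


def default_horizon(time, event) -> float:
    """The KM median survival time (the usual case/control cut-off)."""
    km = km_estimate(time, event)
    if km.median_survival is None:
        raise ValueError("survival never reaches 0.5; specify a horizon explicitly")
    return km.median_survival


def td_roc(scores, time, event, t: float | None = None,
           estimator: str = "exclude_censored") -> ROCCurve:
    """Time-dependent ROC of a risk score at horizon ``t``.

    Raises when the horizon leaves no case or no control.
    """
    if estimator not in ("exclude_censored", "ipcw"):
        raise ValueError(f"unknown estimator {estimator!r}")
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not (scores.shape == time.shape == event.shape):
        raise ValueError("scores, time and event must have equal length")
    if t is None:
        t = default_horizon(time, event)
    if not (time.min() <= t <= time.max()):
        raise ValueError("horizon t must lie within the observed time range")

    case = (event == 1) & (time <= t)
    control = time > t
    if estimator == "ipcw":
        cens_km = km_estimate(time, 1 - event)  # censoring survival G
        w = np.zeros_like(scores)
        for i in np.nonzero(case)[0]:
            g = cens_km.survival_before(time[i])
            w[i] = 1.0 / g if g > 0 else 0.0
        g_t = cens_km.survival_at(t)
        if g_t > 0:
            w[control] = 1.0 / g_t
    else:
        w = np.zeros_like(scores)
        w[case | control] = 1.0  # censored before t dropped

    case_w = np.where(case, w, 0.0)
    ctrl_w = np.where(control, w, 0.0)
    W_case = case_w.sum()
    W_ctrl = ctrl_w.sum()
    n_cases = int(case.sum())
    n_controls = int(control.sum())
    if n_cases == 0 or n_controls == 0 or W_case == 0 or W_ctrl == 0:
        raise ValueError(f"no cases or no controls at horizon t={t:g}")

    # sweep thresholds from the highest score down; tied scores form one step
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    uniq, starts = np.unique(-s_sorted, return_index=True)
    thresholds = -uniq  # descending
    cum_case = np.cumsum(case_w[order])
    cum_ctrl = np.cumsum(ctrl_w[order])
    ends = np.append(starts[1:], len(s_sorted)) - 1
    tpr = np.concatenate([[0.0], cum_case[ends] / W_case])
    fpr = np.concatenate([[0.0], cum_ctrl[ends] / W_ctrl])
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(float(t), thresholds, tpr, fpr, auc, estimator,
                    n_cases, n_controls)


def compare_signatures(
    cohort: CohortBundle, candidates: dict, t: float | None = None,
    estimator: str = "exclude_censored",
) -> pd.DataFrame:
    """AUC of several named score vectors on the same samples and horizon.

    ``candidates`` maps a name to a per-sample score Series (risk scores,
    clinical variables used directly as scores, or alternative panels).
    Evaluation is restricted to samples shared by every candidate; one row
    per candidate, sorted by AUC descending.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate scores to compare")
    shared = list(cohort.sample_ids)
    for name, s in candidates.items():
        s = pd.Series(s)
        shared = [x for x in shared if x in s.index and np.isfinite(s[x])]
    if not shared:
        raise ValueError("candidates share no scored samples")
    surv = cohort.survival.loc[shared]
    time = surv["time"].to_numpy(float)
    event = surv["event"].to_numpy(int)
    if t is None:
        t = default_horizon(time, event)
    rows = []
    for name, s in candidates.items():
        roc = td_roc(pd.Series(s).loc[shared].to_numpy(float), time, event,
                     t=t, estimator=estimator)
        rows.append({"signature": name, "auc": roc.auc, "t": roc.horizon,
                     "n_cases": roc.n_cases, "n_controls": roc.n_controls})
    return (
        pd.DataFrame(rows)
        .sort_values("auc", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
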