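"""The lncRNA risk-score model.

For one transcription factor with regulon {lnc_1, ..., lnc_n}, each lncRNA
gets a coefficient beta_i from a *univariate* Cox fit of survival on its
expression alone, and each patient s gets

    RiskScore(s) = sum_i beta_i * Exp(lnc_i, s)

Patients are dichotomized at the training cohort's median risk score
(scores exactly at the cut-point go to the LOW group, which makes an odd-n
cohort split ceil/floor deterministically).  A signature is evaluated by
the log-rank test between the two groups plus a Cox fit of the continuous
score, standardized so its hazard ratio is per standard deviation of score.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import CohortBundle
from .survival import CoxResult, KMCurve, LogRankResult, cox_fit, km_estimate, logrank_test

logger = logging.getLogger("lncrisk")

__all__ = [
    "RiskModel",
    "RiskAssignment",
    "SignatureEvaluation",
    "fit_risk_model",
    "compute_risk_scores",
    "assign_groups",
    "evaluate_signature",
]


@dataclass
class RiskModel:
    """A trained per-TF signature: ordered lncRNAs, their univariate Cox
    coefficients, and the training median cut-point."""

    tf_id: str
    lnc_ids: list
    betas: np.ndarray
    cutpoint: float
    training_cohort: str = ""
    endpoint: str = "OS"
    dropped: list = field(default_factory=list)

    def __post_init__(self):
        self.betas = np.asarray(self.betas, dtype=float)
        if len(self.lnc_ids) != self.betas.size or self.betas.size < 1:
            raise ValueError("need one beta per lncRNA, at least one member")
        if not np.isfinite(self.cutpoint):
            raise ValueError("cut-point must be finite")

    def to_json(self, path=None) -> str:
        doc = {
            "tf_id": self.tf_id,
            "lnc_ids": list(self.lnc_ids),
            "betas": [float(b) for b in self.betas],
            "cutpoint": float(self.cutpoint),
            "training_cohort": self.training_cohort,
            "endpoint": self.endpoint,
            "dropped": list(self.dropped),
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "RiskModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            tf_id=doc["tf_id"],
            lnc_ids=doc["lnc_ids"],
            betas=np.asarray(doc["betas"], dtype=float),
            cutpoint=doc["cutpoint"],
            training_cohort=doc.get("training_cohort", ""),
            endpoint=doc.get("endpoint", "OS"),
            dropped=doc.get("dropped", []),
        )


@dataclass
class RiskAssignment:
    """Per-sample risk scores and high/low group labels."""

    sample_ids: list
    scores: np.ndarray
    group: np.ndarray  # "high" / "low"
    cutpoint: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"score": self.scores, "group": self.group},
            index=pd.Index(self.sample_ids, name="sample"),
        )


@dataclass
class SignatureEvaluation:
    """Survival evaluation of one signature on one cohort."""

    assignment: RiskAssignment
    logrank: LogRankResult
    cox_score: CoxResult  # HR per SD of the (standardized) continuous score
    km_high: KMCurve
    km_low: KMCurve

    @property
    def hr_per_sd(self) -> float:
        return float(self.cox_score.hr[0])

    @property
    def logrank_p(self) -> float:
        return float(self.logrank.p)


def fit_risk_model(
    bundle: CohortBundle,
    tf_id: str,
    regulon,
    endpoint: str | None = None,
) -> RiskModel:
    """Fit the per-TF signature on a training cohort.

    Each regulon member present (and non-constant) in the expression matrix
    gets its own univariate Cox coefficient; absent or degenerate members
    are dropped and recorded.  The cut-point is the median training score.
    """
    time, event = bundle.time_event()
    if event.sum() == 0:
        raise ValueError("training cohort has no observed events")
    expr = bundle.expression
    betas, kept, dropped = [], [], []
    for lnc in regulon:
        if lnc not in expr.index:
            dropped.append(lnc)
            continue
        x = expr.loc[lnc].to_numpy(dtype=float)
        if x.std() == 0:
            dropped.append(lnc)
            continue
        fit = cox_fit(time, event, x, names=[lnc])
        betas.append(float(fit.beta[0]))
        kept.append(lnc)
    if dropped:
        logger.info(
            "fit_risk_model[%s]: dropped %d unusable regulon members", tf_id, len(dropped)
        )
    if not kept:
        raise ValueError(f"no usable regulon member for TF {tf_id!r}")
    model = RiskModel(
        tf_id=tf_id,
        lnc_ids=kept,
        betas=np.asarray(betas),
        cutpoint=0.0,
        training_cohort=bundle.name,
        endpoint=endpoint or str(bundle.survival.get("endpoint", pd.Series(["OS"])).iloc[0]),
        dropped=dropped,
    )
    scores = compute_risk_scores(model, expr)
    model.cutpoint = float(np.median(scores.to_numpy()))
    return model


def compute_risk_scores(model: RiskModel, expr: pd.DataFrame) -> pd.Series:
    """Risk score per sample: the beta-weighted sum of member expression.

    Members absent from the matrix are dropped (warned, not renormalized);
    it is an error if none remain.
    """
    present = [i for i, l in enumerate(model.lnc_ids) if l in expr.index]
    if not present:
        raise ValueError(
            f"none of the {len(model.lnc_ids)} model lncRNAs are in the matrix"
        )
    if len(present) < len(model.lnc_ids):
        logger.warning(
            "compute_risk_scores[%s]: %d of %d model members missing from matrix",
            model.tf_id, len(model.lnc_ids) - len(present), len(model.lnc_ids),
        )
    lncs = [model.lnc_ids[i] for i in present]
    b = model.betas[present]
    scores = b @ expr.loc[lncs].to_numpy(dtype=float)
    return pd.Series(scores, index=expr.columns, name="score")


def assign_groups(scores: pd.Series, cutpoint="median") -> RiskAssignment:
    """Dichotomize scores into high (> cut-point) / low (<= cut-point).

    ``cutpoint="median"`` uses the within-cohort median, giving equal-sized
    groups for even n of distinct scores, and a one-larger LOW group for odd
    n.  All-identical scores cannot be split and raise.
    """
    values = scores.to_numpy(dtype=float)
    if values.size < 2:
        raise ValueError("need at least two samples to split")
    if np.all(values == values[0]):
        raise ValueError("all risk scores identical; no split possible")
    cut = float(np.median(values)) if isinstance(cutpoint, str) else float(cutpoint)
    group = np.where(values > cut, "high", "low")
    if len(set(group)) < 2:
        raise ValueError("cut-point produces a single group; no split possible")
    return RiskAssignment(list(scores.index), values, group, cut)


def evaluate_signature(
    model: RiskModel,
    bundle: CohortBundle,
    assignment: RiskAssignment | None = None,
) -> SignatureEvaluation:
    """Evaluate a signature on a cohort.

    By default scores come from the model and the split uses the model's
    cut-point (the training median, i.e. the in-cohort median when the
    bundle is the training cohort).  A precomputed ``assignment`` (e.g.
    from a z-score transfer) can be supplied instead.
    """
    if assignment is None:
        scores = compute_risk_scores(model, bundle.expression)
        assignment = assign_groups(scores, cutpoint=model.cutpoint)
    time, event = bundle.time_event()
    lr = logrank_test(time, event, assignment.group)
    z = (assignment.scores - assignment.scores.mean()) / assignment.scores.std(ddof=1)
    cox = cox_fit(time, event, z, names=["risk_score_per_sd"])
    hi = assignment.group == "high"
    km_high = km_estimate(time[hi], event[hi])
    km_low = km_estimate(time[~hi], event[~hi])
    return SignatureEvaluation(assignment, lr, cox, km_high, km_low)
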