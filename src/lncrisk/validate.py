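"""Independent-cohort validation, clinical stratification and consistency.

Two validation modes mirror the two natural readings of cross-cohort
validation of a risk signature:

* **refit** — rebuild the model (coefficients and median cut-point) inside
  the validation cohort, then evaluate there; the primary analysis.
* **transfer** — score the validation cohort with the *training*
  coefficients, z-normalize scores within each cohort (sample SD, n-1) and
  split at the training median expressed on the z scale; this carries the
  training cut-point across cohorts with different expression scales and is
  invariant to any affine transform of the validation scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CohortBundle
from .risk import (
    RiskAssignment,
    RiskModel,
    SignatureEvaluation,
    assign_groups,
    compute_risk_scores,
    evaluate_signature,
    fit_risk_model,
)
from .survival import CoxResult, cox_fit

logger = logging.getLogger("lncrisk")

__all__ = [
    "TransferredModel",
    "StratumResult",
    "ConsistencyRecord",
    "validate_refit",
    "validate_transfer",
    "transfer_assignment",
    "stratify",
    "multivariate_adjust",
    "risk_direction_consistency",
]


@dataclass
class TransferredModel:
    """A trained model plus the per-cohort z parameters used to carry its
    cut-point onto another cohort's score scale."""

    model: RiskModel
    train_mean: float
    train_sd: float

    @property
    def transferred_cutpoint(self) -> float:
        """The training median cut-point expressed on the z scale."""
        return (self.model.cutpoint - self.train_mean) / self.train_sd


@dataclass
class StratumResult:
    stratum: str
    variable: str
    n: int
    evaluation: SignatureEvaluation | None
    note: str = ""


@dataclass
class ConsistencyRecord:
    lnc_id: str
    signs: dict  # cohort name -> sign of beta (+1 / -1)
    consistent: bool


def validate_refit(
    tf_id: str, regulon, cohort: CohortBundle
) -> SignatureEvaluation:
    """Rebuild the signature inside the validation cohort and evaluate it
    there (coefficients and median cut-point both refit)."""
    model = fit_risk_model(cohort, tf_id, regulon)
    return evaluate_signature(model, cohort)


def transfer_assignment(model: RiskModel, cohort: CohortBundle,
                        train_scores) -> RiskAssignment:
    """Group assignment on a validation cohort via z-normalized transfer.

    Scores use the training betas; both the training scores and the
    validation scores are z-normalized within their own cohorts, and the
    split threshold is the z-transformed training median.
    """
    val_scores = compute_risk_scores(model, cohort.expression)
    v = val_scores.to_numpy()
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("validation risk scores have zero variance")
    z = (v - v.mean()) / sd
    t = np.asarray(train_scores, dtype=float)
    t_sd = t.std(ddof=1)
    if t_sd == 0:
        raise ValueError("training risk scores have zero variance")
    z_cut = (model.cutpoint - t.mean()) / t_sd
    group = np.where(z > z_cut, "high", "low")
    if len(set(group)) < 2:
        raise ValueError("transferred cut-point produces a single group")
    return RiskAssignment(list(val_scores.index), z, group, float(z_cut))


def validate_transfer(
    model: RiskModel,
    cohort: CohortBundle,
    training: CohortBundle | None = None,
    train_scores: np.ndarray | None = None,
) -> SignatureEvaluation:
    """Evaluate a trained model on another cohort via cut-point transfer.

    Provide either the training bundle (scores are recomputed from it) or
    the raw training scores.
    """
    if train_scores is None:
        if training is None:
            raise ValueError("need the training bundle or its scores")
        train_scores = compute_risk_scores(model, training.expression).to_numpy()
    assignment = transfer_assignment(model, cohort, train_scores=train_scores)
    return evaluate_signature(model, cohort, assignment=assignment)


_STRATA_RULES = {
    "grade": ("grade G1/G2", "grade G3/G4", lambda v: v <= 2),
    "stage": ("stage I/II", "stage III/IV", lambda v: v <= 2),
    "residual": ("residual <=10 mm", "residual >10 mm", lambda v: v <= 10),
}


def stratify(cohort: CohortBundle, variable: str) -> dict:
    """Partition a cohort's samples on one clinical variable.

    age -> <= median vs > median; grade -> G1/G2 vs G3/G4; stage -> I/II vs
    III/IV; residual -> <=10 mm vs >10 mm.  Samples missing the variable
    are excluded (logged); returns ``{stratum_label: [sample ids]}`` with
    empty strata omitted.
    """
    if variable not in ("age", "grade", "stage", "residual"):
        raise ValueError(f"unknown stratification variable {variable!r}")
    if variable not in cohort.survival.columns:
        raise ValueError(f"cohort {cohort.name!r} has no {variable!r} column")
    col = pd.to_numeric(cohort.survival[variable], errors="coerce")
    missing = int(col.isna().sum())
    if missing:
        logger.info("stratify[%s]: excluded %d samples missing %s",
                    cohort.name, missing, variable)
    obs = col.dropna()
    if obs.empty:
        raise ValueError(f"no sample has an observed {variable!r}")
    if variable == "age":
        med = float(obs.median())
        lo_lab, hi_lab = f"age <= {med:g}", f"age > {med:g}"
        in_lo = obs <= med
    else:
        lo_lab, hi_lab, rule = _STRATA_RULES[variable]
        in_lo = obs.map(rule)
    out = {}
    lo = list(obs.index[in_lo])
    hi = list(obs.index[~in_lo])
    if lo:
        out[lo_lab] = lo
    else:
        logger.warning("stratify[%s]: empty stratum %s skipped", cohort.name, lo_lab)
    if hi:
        out[hi_lab] = hi
    else:
        logger.warning("stratify[%s]: empty stratum %s skipped", cohort.name, hi_lab)
    return out


def subset_bundle(cohort: CohortBundle, sample_ids) -> CohortBundle:
    """A cohort restricted to the given samples (order preserved)."""
    ids = [s for s in cohort.sample_ids if s in set(sample_ids)]
    return CohortBundle(
        cohort.expression[ids], cohort.survival.loc[ids], name=cohort.name
    )


def stratified_evaluation(
    model: RiskModel, cohort: CohortBundle, variable: str
) -> list:
    """Evaluate the signature separately within each clinical stratum.

    Scores use the trained coefficients; each stratum is split at its own
    median score, so the analysis is well defined on cohorts whose
    expression scale differs from the training cohort's.  Strata too
    degenerate to evaluate (single group, no events) are returned with a
    note instead of an evaluation.
    """
    results = []
    for label, ids in stratify(cohort, variable).items():
        sub = subset_bundle(cohort, ids)
        try:
            scores = compute_risk_scores(model, sub.expression)
            ev = evaluate_signature(model, sub,
                                    assignment=assign_groups(scores, "median"))
            results.append(StratumResult(label, variable, len(ids), ev))
        except ValueError as exc:
            logger.warning("stratum %s skipped: %s", label, exc)
            results.append(StratumResult(label, variable, len(ids), None, note=str(exc)))
    return results


def multivariate_adjust(
    cohort: CohortBundle, scores: pd.Series, covariates
) -> CoxResult:
    """Joint Cox fit of the risk score plus clinical covariates.

    The score enters per SD; ordinal clinical variables enter as their
    integer codes (one hazard ratio per variable), age as-is.  Samples
    missing any requested covariate are dropped (logged).  Exactly
    collinear covariate pairs raise an error naming the pair.
    """
    covariates = list(covariates)
    for c in covariates:
        if c not in cohort.survival.columns:
            raise ValueError(f"cohort {cohort.name!r} has no covariate {c!r}")
    df = cohort.survival[["time", "event", *covariates]].copy()
    df["score"] = scores.reindex(df.index)
    before = len(df)
    df = df.dropna()
    if len(df) < before:
        logger.info("multivariate_adjust[%s]: dropped %d samples with missing values",
                    cohort.name, before - len(df))
    if int(df["event"].sum()) < 10:
        raise ValueError("multivariate adjustment needs at least 10 events")
    names = ["score", *covariates]
    X = np.column_stack(
        [(df["score"] - df["score"].mean()) / df["score"].std(ddof=1)]
        + [df[c].to_numpy(dtype=float) for c in covariates]
    )
    # exact collinearity check, pairwise
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            xi, xj = X[:, i], X[:, j]
            if xi.std() == 0 or xj.std() == 0:
                continue
            r = np.corrcoef(xi, xj)[0, 1]
            if abs(r) > 1 - 1e-10:
                raise ValueError(
                    f"covariates {names[i]!r} and {names[j]!r} are collinear"
                )
    return cox_fit(
        df["time"].to_numpy(), df["event"].to_numpy(int), X, names=names
    )


def risk_direction_consistency(models: dict, lnc_universe=None) -> list:
    """Compare per-lncRNA coefficient signs across per-cohort models.

    ``models`` maps cohort name -> RiskModel (same TF refit per cohort).  A
    lncRNA is *consistent* when it carries the same nonzero beta sign in
    every cohort; lncRNAs absent from any cohort's model are excluded.
    """
    if len(models) < 2:
        raise ValueError("consistency needs at least two cohorts")
    per_cohort = {
        name: dict(zip(m.lnc_ids, m.betas)) for name, m in models.items()
    }
    if lnc_universe is None:
        lnc_universe = sorted({l for b in per_cohort.values() for l in b})
    records = []
    for lnc in lnc_universe:
        if not all(lnc in b for b in per_cohort.values()):
            continue
        signs = {name: int(np.sign(b[lnc])) for name, b in per_cohort.items()}
        vals = set(signs.values())
        consistent = len(vals) == 1 and 0 not in vals
        records.append(ConsistencyRecord(lnc, signs, consistent))
    return records
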