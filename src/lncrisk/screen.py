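"""Genome-wide TF screen: score every regulon, rank TFs by prognosis.

For each TF in the network the risk model is fit (univariate Cox betas,
median cut-point) and the signature is evaluated by log-rank on the
high/low split plus a per-SD Cox fit of the continuous score.  TFs are
ranked by log-rank p ascending, ties broken by |log HR| descending then
TF id; a BH-adjusted q across the TF family is reported alongside the raw
ranking.  A *baseline* screen — a univariate Cox fit of each TF's own
expression row, i.e. the pre-model comparison — is also provided.

In-sample evaluation (fit and evaluate on the same cohort) is the default
screening mode; passing a held-out evaluation cohort switches to cut-point
transfer, which gives calibrated type-I error under the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CohortBundle
from .network import TFTargetNetwork, bh_adjust
from .risk import RiskModel, compute_risk_scores, evaluate_signature, fit_risk_model
from .survival import cox_fit
from .validate import validate_transfer

logger = logging.getLogger("lncrisk")

__all__ = ["TFScreenResult", "baseline_tf_screen", "screen_tfs", "top_k", "screen_table"]


@dataclass
class TFScreenResult:
    tf_id: str
    n_targets: int
    hr_per_sd: float
    ci_low: float
    ci_high: float
    logrank_p: float
    cox_p: float
    rank: int = 0
    bh_q: float = float("nan")
    baseline_p: float | None = None
    model: RiskModel | None = None


def baseline_tf_screen(bundle: CohortBundle, tf_ids) -> dict:
    """Univariate Cox fit of each TF's own expression row (pre-model
    baseline).  TFs absent from the matrix or with constant expression are
    skipped with a log entry.  Returns ``{tf_id: CoxResult}``."""
    time, event = bundle.time_event()
    out: dict = {}
    skipped = 0
    for tf in tf_ids:
        if tf not in bundle.expression.index:
            skipped += 1
            continue
        x = bundle.expression.loc[tf].to_numpy(dtype=float)
        if x.std() == 0:
            skipped += 1
            continue
        out[tf] = cox_fit(time, event, x, names=[tf])
    if skipped:
        logger.info("baseline_tf_screen: skipped %d absent/constant TFs", skipped)
    return out


def screen_tfs(
    bundle: CohortBundle,
    network: TFTargetNetwork,
    eval_bundle: CohortBundle | None = None,
    with_baseline: bool = False,
) -> list:
    """Fit and evaluate the risk signature of every TF in the network.

    ``eval_bundle=None`` evaluates in-sample on the training cohort;
    otherwise the trained model is transferred (z-normalized cut-point) to
    the held-out cohort and evaluated there.
    """
    if not network.regulons:
        raise ValueError("network contains no TF with a usable regulon")
    baseline = (
        baseline_tf_screen(bundle, list(network.regulons)) if with_baseline else {}
    )
    results = []
    for tf in sorted(network.regulons):
        regulon = network.regulons[tf]
        try:
            model = fit_risk_model(bundle, tf, regulon)
            if eval_bundle is None:
                ev = evaluate_signature(model, bundle)
            else:
                train_scores = compute_risk_scores(model, bundle.expression).to_numpy()
                ev = validate_transfer(model, eval_bundle, train_scores=train_scores)
        except ValueError as exc:
            logger.warning("screen: TF %s skipped (%s)", tf, exc)
            continue
        cox = ev.cox_score
        base = baseline.get(tf)
        results.append(
            TFScreenResult(
                tf_id=tf,
                n_targets=len(model.lnc_ids),
                hr_per_sd=float(cox.hr[0]),
                ci_low=float(cox.ci_low[0]),
                ci_high=float(cox.ci_high[0]),
                logrank_p=ev.logrank_p,
                cox_p=float(cox.p[0]),
                baseline_p=float(base.p[0]) if base is not None else None,
                model=model,
            )
        )
    if not results:
        raise ValueError("no TF could be screened")
    results.sort(
        key=lambda r: (r.logrank_p, -abs(np.log(r.hr_per_sd)), r.tf_id)
    )
    q = bh_adjust(np.array([r.logrank_p for r in results]))
    for i, r in enumerate(results):
        r.rank = i + 1
        r.bh_q = float(q[i])
    return results


def top_k(results, k: int = 10) -> list:
    """The first k TFs by rank; all of them (with a warning) if k exceeds
    the number screened."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(results):
        logger.warning("top_k: requested %d of %d screened TFs", k, len(results))
        k = len(results)
    return sorted(results, key=lambda r: r.rank)[:k]


def screen_table(results) -> pd.DataFrame:
    """Ranked screen results as a tidy DataFrame (for TSV output)."""
    return pd.DataFrame(
        [
            {
                "tf": r.tf_id,
                "n_targets": r.n_targets,
                "hr_per_sd": r.hr_per_sd,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "logrank_p": r.logrank_p,
                "cox_p": r.cox_p,
                "bh_q": r.bh_q,
                "baseline_p": r.baseline_p,
                "rank": r.rank,
            }
            for r in sorted(results, key=lambda x: x.rank)
        ]
    )
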