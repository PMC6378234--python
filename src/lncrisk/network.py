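"""TF-lncRNA regulon construction by co-expression filtering.

Candidate binding pairs (TF -> set of lncRNAs, e.g. from ChIP-seq-derived
resources, supplied as GMT) are confirmed or rejected by Pearson correlation
of the TF's expression with each candidate target across the cohort.  An
edge is kept when r > r_min (default 0, positive co-expression) and the
Benjamini-Hochberg FDR over the whole candidate family is < fdr_max
(default 0.05).  TFs whose regulon empties out are removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .io import CohortBundle

logger = logging.getLogger("lncrisk")

__all__ = [
    "CandidateEdge",
    "TFTargetNetwork",
    "pearson_correlation",
    "bh_adjust",
    "build_network",
]


@dataclass
class CandidateEdge:
    tf_id: str
    lnc_id: str
    r: float
    p: float
    fdr: float
    kept: bool


@dataclass
class TFTargetNetwork:
    """Correlation-confirmed regulon network.

    ``edges`` holds only the retained edges; ``regulons`` maps each TF to
    its ordered, duplicate-free target list.  ``edge_table`` records every
    tested candidate pair (kept or not) for reporting.
    """

    edges: list
    regulons: dict
    edge_table: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_tfs(self) -> int:
        return len(self.regulons)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def lnc_ids(self) -> list:
        seen: dict = {}
        for e in self.edges:
            seen.setdefault(e.lnc_id, None)
        return list(seen)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided p-value from the t-transform (n-2 df).

    Requires length >= 3 and nonzero variance in both vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 3:
        raise ValueError("correlation needs at least 3 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = np.sqrt((dx * dx).sum())
    sy = np.sqrt((dy * dy).sum())
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for a zero-variance vector")
    r = float(np.clip((dx * dy).sum() / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * _stats.t.sf(abs(t), n - 2))
    return r, p


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvals must be 1-D")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _row_correlations(tf_row: np.ndarray, target_rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Pearson r + t-transform p of one row against many rows."""
    n = tf_row.size
    dx = tf_row - tf_row.mean()
    dy = target_rows - target_rows.mean(axis=1, keepdims=True)
    sx = np.sqrt((dx * dx).sum())
    sy = np.sqrt((dy * dy).sum(axis=1))
    r = np.clip((dy @ dx) / (sx * sy), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r * r, 1e-300, None))
    p = 2.0 * _stats.t.sf(np.abs(t), n - 2)
    p[np.abs(r) == 1.0] = 0.0
    return r, p


def build_network(
    bundle: CohortBundle,
    candidates: dict,
    r_min: float = 0.0,
    fdr_max: float = 0.05,
    family: str = "global",
) -> TFTargetNetwork:
    """Filter candidate TF -> lncRNA pairs by co-expression in one cohort.

    Parameters
    ----------
    candidates
        mapping ``tf_id -> iterable of candidate lnc ids`` (a parsed GMT).
    r_min, fdr_max
        retention thresholds: strict inequalities ``r > r_min`` and
        ``fdr < fdr_max``.
    family
        ``"global"`` adjusts p-values over all tested pairs in one BH
        family; ``"per_tf"`` adjusts within each TF's candidate list.

    TFs or lncRNAs absent from the expression matrix, and constant
    expression rows, are dropped with a logged count.  Raises if no
    candidate pair is testable.
    """
    if family not in ("global", "per_tf"):
        raise ValueError(f"unknown FDR family {family!r}")
    expr = bundle.expression
    present = set(expr.index)
    values = expr.to_numpy()
    row_of = {g: i for i, g in enumerate(expr.index)}
    constant = {g for g, i in row_of.items() if values[i].std() == 0}
    if constant:
        logger.info("build_network: excluded %d constant expression rows", len(constant))

    rows = []  # (tf, lnc, r, p)
    n_missing_tf = n_missing_lnc = 0
    for tf, lncs in candidates.items():
        if tf not in present or tf in constant:
            n_missing_tf += 1
            continue
        usable, seen = [], set()
        for l in lncs:
            if l in seen:
                continue
            seen.add(l)
            if l in present and l not in constant and l != tf:
                usable.append(l)
            else:
                n_missing_lnc += 1
        if not usable:
            continue
        r, p = _row_correlations(
            values[row_of[tf]], values[[row_of[l] for l in usable]]
        )
        rows.extend(zip([tf] * len(usable), usable, r, p))
    if n_missing_tf or n_missing_lnc:
        logger.info(
            "build_network: dropped %d TFs and %d candidate targets absent/constant",
            n_missing_tf, n_missing_lnc,
        )
    if not rows:
        raise ValueError("no candidate TF-lncRNA pair is testable in this cohort")

    table = pd.DataFrame(rows, columns=["tf", "lnc", "r", "p"])
    if family == "global":
        table["fdr"] = bh_adjust(table["p"].to_numpy())
    else:
        table["fdr"] = (
            table.groupby("tf", sort=False)["p"]
            .transform(lambda s: bh_adjust(s.to_numpy()))
        )
    table["kept"] = (table["r"] > r_min) & (table["fdr"] < fdr_max)

    edges = [
        CandidateEdge(t.tf, t.lnc, float(t.r), float(t.p), float(t.fdr), bool(t.kept))
        for t in table.itertuples()
        if t.kept
    ]
    regulons: dict = {}
    for e in edges:
        regulons.setdefault(e.tf_id, []).append(e.lnc_id)
    logger.info(
        "build_network: retained %d of %d candidate edges across %d TFs",
        len(edges), len(table), len(regulons),
    )
    return TFTargetNetwork(edges=edges, regulons=regulons, edge_table=table)
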