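"""Reading, writing and aligning cohort data.

File conventions (all plain text, locale-independent, dot decimal):

* expression: TSV, genes in rows, first column gene id, header = sample ids
* clinical:   TSV with mandatory columns ``sample``, ``time``, ``event`` and
  optional ``endpoint``, ``age``, ``stage``, ``grade``, ``residual``,
  ``lymph`` (ordinal clinical codes; missing values allowed)
* probe map:  2-column TSV ``probe<TAB>gene`` (no header required)
* gene sets:  GMT (set name, description, members)

An aligned expression + clinical pair is a :class:`CohortBundle`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("lncrisk")

__all__ = [
    "CohortBundle",
    "read_expression",
    "write_expression",
    "read_clinical",
    "write_clinical",
    "read_probe_map",
    "collapse_probes",
    "align_cohort",
    "read_gmt",
    "write_gmt",
]

CLINICAL_COVARIATES = ("age", "stage", "grade", "residual", "lymph")


@dataclass
class CohortBundle:
    """An expression matrix and survival table over identical, identically
    ordered samples.

    ``expression``: genes x samples DataFrame (index = gene ids, columns =
    sample ids).  ``survival``: samples x variables DataFrame (index = sample
    ids) with at least ``time`` and ``event`` columns.
    """

    expression: pd.DataFrame
    survival: pd.DataFrame
    name: str = "cohort"

    def __post_init__(self):
        if list(self.expression.columns) != list(self.survival.index):
            raise ValueError(
                f"cohort {self.name!r}: expression samples and survival samples "
                "differ or are ordered differently; use align_cohort()"
            )

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def sample_ids(self) -> list:
        return list(self.expression.columns)

    def time_event(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.survival["time"].to_numpy(dtype=float),
            self.survival["event"].to_numpy(dtype=int),
        )


def _check_unique(ids: Iterable, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id {i!r}")
        seen.add(i)


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples expression TSV.

    Raises ``ValueError`` naming the offending id on duplicate gene or
    sample ids, and naming the cell on a non-numeric value.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    try:
        values = df.astype(float)
    except ValueError:
        for gene in df.index:
            for sample in df.columns:
                try:
                    float(df.loc[gene, sample])
                except ValueError:
                    raise ValueError(
                        f"non-numeric expression value {df.loc[gene, sample]!r} "
                        f"at gene {gene!r}, sample {sample!r}"
                    ) from None
        raise
    if not np.all(np.isfinite(values.to_numpy())):
        bad = np.argwhere(~np.isfinite(values.to_numpy()))[0]
        raise ValueError(
            f"non-finite expression value at gene {values.index[bad[0]]!r}, "
            f"sample {values.columns[bad[1]]!r}"
        )
    values.index.name = "gene"
    return values


def write_expression(expr: pd.DataFrame, path) -> None:
    expr = expr.copy()
    expr.index.name = "gene"
    expr.to_csv(path, sep="\t", float_format="%.10g")


def read_clinical(path) -> pd.DataFrame:
    """Read a clinical/survival TSV keyed by the ``sample`` column.

    Validates time > 0 and event in {0, 1}; optional covariates are kept as
    numeric with missing values preserved as NaN.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "time", "event"):
        if col not in df.columns:
            raise ValueError(f"clinical table missing mandatory column {col!r}")
    _check_unique(df["sample"], "sample")
    df = df.set_index("sample")
    df["time"] = df["time"].astype(float)
    df["event"] = df["event"].astype(int)
    if (df["time"] <= 0).any():
        bad = df.index[df["time"] <= 0][0]
        raise ValueError(f"non-positive survival time for sample {bad!r}")
    if not df["event"].isin((0, 1)).all():
        bad = df.index[~df["event"].isin((0, 1))][0]
        raise ValueError(f"event must be 0/1; offending sample {bad!r}")
    for col in CLINICAL_COVARIATES:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def write_clinical(surv: pd.DataFrame, path) -> None:
    out = surv.copy()
    out.index.name = "sample"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_probe_map(path) -> dict:
    """Read a 2-column probe -> gene TSV into a dict.

    A probe listed with two different genes is rejected: only uniquely
    mapped probes are usable for collapsing.
    """
    mapping: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed probe-map line: {line!r}")
            probe, gene = parts[0], parts[1]
            if probe == "probe" and gene == "gene":
                continue  # optional header
            if probe in mapping and mapping[probe] != gene:
                raise ValueError(f"probe {probe!r} maps to multiple genes")
            mapping[probe] = gene
    return mapping


def collapse_probes(probe_matrix: pd.DataFrame, probe_map: Mapping) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level by the arithmetic mean.

    Each gene row is the plain mean over the rows of its (uniquely mapped)
    probes.  Probes absent from ``probe_map`` are dropped and counted in the
    log.  A probe mapped to more than one gene is an error.
    """
    for probe, gene in probe_map.items():
        if isinstance(gene, (set, frozenset, list, tuple)):
            raise ValueError(f"probe {probe!r} maps to multiple genes")
    keep = [p for p in probe_matrix.index if p in probe_map]
    dropped = probe_matrix.shape[0] - len(keep)
    if dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", dropped)
    if not keep:
        raise ValueError("no probe in the matrix is present in the probe map")
    sub = probe_matrix.loc[keep]
    genes = pd.Index([probe_map[p] for p in keep], name="gene")
    collapsed = sub.groupby(genes, sort=False).mean()
    collapsed = collapsed.loc[pd.unique(genes)]  # deterministic first-seen order
    return collapsed


def align_cohort(expr: pd.DataFrame, surv: pd.DataFrame, name: str = "cohort") -> CohortBundle:
    """Restrict expression and survival to their shared samples, same order.

    Order follows the expression matrix's column order.  Idempotent; raises
    on an empty intersection.
    """
    shared = [s for s in expr.columns if s in set(surv.index)]
    if not shared:
        raise ValueError(
            f"cohort {name!r}: expression and survival share no samples"
        )
    dropped_expr = expr.shape[1] - len(shared)
    dropped_surv = surv.shape[0] - len(shared)
    if dropped_expr or dropped_surv:
        logger.info(
            "align_cohort[%s]: dropped %d expression-only and %d survival-only samples",
            name, dropped_expr, dropped_surv,
        )
    return CohortBundle(expr[shared], surv.loc[shared], name=name)


def read_gmt(path) -> dict:
    """Read a GMT file into an ordered ``{set_name: [members...]}`` dict."""
    sets: dict = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need name, desc, members): {line!r}")
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r}")
            members = [m for m in parts[2:] if m]
            sets[name] = members
    return sets


def write_gmt(sets: Mapping, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([str(name), description, *map(str, members)]) + "\n")
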