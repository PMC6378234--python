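"""Synthetic multi-cohort survival studies with planted TF regulons.

The generator emulates the data model the pipeline assumes: per cohort,
each TF has a latent activity per sample; the TF's own expression is a
noisy readout of that activity and each target lncRNA mixes the activity
with independent noise at co-expression weight ``w`` (so two targets of
the same TF correlate at about w^2).  Survival follows a proportional-
hazards law driven by the planted TF's targets, with effects gamma defined
per standard deviation of expression, exponential baseline hazard and
independent exponential censoring calibrated to a target censoring
fraction via the closed form c / (h0 + c).  Each cohort finally receives
its own affine location/scale shift in expression, mimicking cross-
platform differences; the planted truth is unchanged because effects act
on standardized expression.

Cohort sizes default to the four ovarian-carcinoma cohort sizes the
pipeline is aimed at (399, 107, 278, 75).  A single global seed drives a
hierarchical seed tree so each cohort is individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CohortBundle, write_clinical, write_expression, write_gmt

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_study",
    "simulate_null_study",
    "expected_censoring_rate",
    "write_study",
]


@dataclass
class SimulationConfig:
    """Knobs of the study generator; defaults are the study conditions.

    gamma is the planted log-hazard effect per SD of expression for every
    target of each planted TF; baseline_hazard is in events per month
    (log(2)/60 puts the baseline median survival at 60 months, a realistic
    serous ovarian-carcinoma scale); censoring is the target censored
    fraction under the null.
    """

    seed: int = 0
    cohort_sizes: tuple = (399, 107, 278, 75)
    cohort_names: tuple | None = None
    n_lncrnas: int = 300
    n_tfs: int = 50
    targets_per_tf: int = 10
    decoys_per_tf: int = 10
    coexpression: float = 0.6  # w; corr(TF target, TF activity)
    n_planted: int = 1
    gamma: float = 0.3  # log-hazard per SD of each planted target
    baseline_hazard: float = np.log(2) / 60.0  # h0, per month
    censoring: float = 0.55  # target censored fraction at gamma = 0
    scale_range: tuple = (0.7, 1.5)  # per-cohort expression scale
    shift_range: tuple = (-2.0, 3.0)  # per-cohort expression shift
    tf_noise: float = 0.5  # TF expression = activity + tf_noise * N(0,1)
    baseline: str = "exponential"  # or "weibull"
    weibull_shape: float = 1.5
    endpoint: str = "OS"

    def __post_init__(self):
        if min(self.cohort_sizes) < 2 or self.n_lncrnas < 1 or self.n_tfs < 1:
            raise ValueError("all counts must be >= 1 (cohorts >= 2 samples)")
        if not (0.0 <= self.coexpression < 1.0):
            raise ValueError("coexpression weight w must lie in [0, 1)")
        if not (0.0 < self.censoring < 1.0):
            raise ValueError("censoring target must lie in (0, 1)")
        if self.targets_per_tf > self.n_lncrnas:
            raise ValueError("more targets per TF than lncRNAs")
        if self.baseline not in ("exponential", "weibull"):
            raise ValueError(f"unknown baseline {self.baseline!r}")

    @property
    def tf_ids(self) -> list:
        return [f"TF{i + 1:03d}" for i in range(self.n_tfs)]

    @property
    def lnc_ids(self) -> list:
        return [f"LNC{i + 1:04d}" for i in range(self.n_lncrnas)]

    @property
    def planted_tfs(self) -> list:
        return self.tf_ids[: self.n_planted]


@dataclass
class SimulatedStudy:
    """Generated cohorts plus the ground truth that produced them."""

    cohorts: list  # of CohortBundle
    network_truth: dict  # tf -> list of true target lnc ids
    candidates: dict  # tf -> true targets + decoys (a candidate GMT)
    true_edges: set  # {(tf, lnc)} truly co-expressed pairs
    gamma_truth: dict  # lnc -> planted log-hazard effect per SD
    config: SimulationConfig


def expected_censoring_rate(h0: float, c: float) -> float:
    """P(censoring before event) for independent exponentials: c/(h0+c)."""
    if h0 <= 0 or c <= 0:
        raise ValueError("rates must be positive")
    return c / (h0 + c)


def censoring_rate_for_target(h0: float, target: float) -> float:
    """Censoring hazard c achieving ``target`` censored fraction at gamma=0."""
    return h0 * target / (1.0 - target)


def _draw_targets(rng: np.random.Generator, cfg: SimulationConfig) -> tuple[dict, dict]:
    """Assign true targets (overlap across TFs allowed) and decoys."""
    lncs = np.array(cfg.lnc_ids)
    truth: dict = {}
    drivers: dict = {l: [] for l in cfg.lnc_ids}
    for ti, tf in enumerate(cfg.tf_ids):
        picks = rng.choice(cfg.n_lncrnas, size=cfg.targets_per_tf, replace=False)
        truth[tf] = [str(lncs[j]) for j in sorted(picks)]
        for j in picks:
            drivers[str(lncs[j])].append(ti)
    candidates: dict = {}
    for tf in cfg.tf_ids:
        own = set(truth[tf])
        pool = [l for l in cfg.lnc_ids if l not in own]
        n_dec = min(cfg.decoys_per_tf, len(pool))
        dec = rng.choice(len(pool), size=n_dec, replace=False)
        candidates[tf] = truth[tf] + [pool[j] for j in sorted(dec)]
    return truth, {"drivers": drivers, "candidates": candidates}


def _simulate_cohort(
    seed_seq: np.random.SeedSequence,
    cfg: SimulationConfig,
    name: str,
    n: int,
    drivers: dict,
    gamma_truth: dict,
) -> CohortBundle:
    rng = np.random.default_rng(seed_seq)
    w = cfg.coexpression
    # latent TF activities and expression rows
    act = rng.standard_normal((cfg.n_tfs, n))
    tf_expr = act + cfg.tf_noise * rng.standard_normal((cfg.n_tfs, n))
    lnc_expr = np.empty((cfg.n_lncrnas, n))
    noise = rng.standard_normal((cfg.n_lncrnas, n))
    for i, lnc in enumerate(cfg.lnc_ids):
        d = drivers[lnc]
        if d:
            shared = act[d].sum(axis=0) / np.sqrt(len(d))
            lnc_expr[i] = w * shared + np.sqrt(1.0 - w * w) * noise[i]
        else:
            lnc_expr[i] = noise[i]

    # proportional-hazards survival on standardized (within-cohort) expression
    lp = np.zeros(n)
    for i, lnc in enumerate(cfg.lnc_ids):
        g = gamma_truth.get(lnc, 0.0)
        if g != 0.0:
            x = lnc_expr[i]
            lp += g * (x - x.mean()) / x.std()
    h0 = cfg.baseline_hazard
    rate = h0 * np.exp(lp)
    if cfg.baseline == "exponential":
        T = rng.exponential(1.0 / rate)
    else:  # Weibull via inverse transform; h0 sets the scale
        u = rng.uniform(size=n)
        T = (-np.log(u) / rate) ** (1.0 / cfg.weibull_shape) / h0 ** (
            1.0 - 1.0 / cfg.weibull_shape
        )
    c = censoring_rate_for_target(h0, cfg.censoring)
    C = rng.exponential(1.0 / c, size=n)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    time = np.maximum(time, 1e-6)

    # clinical covariates, independent of expression by construction
    age = rng.normal(60.0, 10.0, size=n).round(1)
    stage = rng.choice([1, 2, 3, 4], size=n, p=[0.05, 0.10, 0.60, 0.25])
    grade = rng.choice([1, 2, 3, 4], size=n, p=[0.05, 0.15, 0.70, 0.10])
    residual = rng.choice([0, 5, 10, 20, 30], size=n, p=[0.30, 0.15, 0.15, 0.20, 0.20])
    lymph = rng.choice([0, 1], size=n, p=[0.60, 0.40])

    # cohort-specific affine shift/scale on all expression rows
    scale = rng.uniform(*cfg.scale_range)
    shift = rng.uniform(*cfg.shift_range)
    samples = [f"{name}_S{j + 1:04d}" for j in range(n)]
    expr = pd.DataFrame(
        np.vstack([tf_expr, lnc_expr]) * scale + shift,
        index=pd.Index(cfg.tf_ids + cfg.lnc_ids, name="gene"),
        columns=samples,
    )
    surv = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "endpoint": cfg.endpoint,
            "age": age,
            "stage": stage,
            "grade": grade,
            "residual": residual,
            "lymph": lymph,
        },
        index=pd.Index(samples, name="sample"),
    )
    return CohortBundle(expr, surv, name=name)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a fully reproducible multi-cohort study from one seed."""
    cfg = config
    root = np.random.SeedSequence(cfg.seed)
    net_seq, *cohort_seqs = root.spawn(1 + len(cfg.cohort_sizes))
    truth, aux = _draw_targets(np.random.default_rng(net_seq), cfg)
    drivers = aux["drivers"]
    candidates = aux["candidates"]
    gamma_truth = {
        lnc: cfg.gamma for tf in cfg.planted_tfs for lnc in truth[tf]
    } if cfg.gamma != 0.0 else {}
    names = cfg.cohort_names or [f"cohort{i + 1}" for i in range(len(cfg.cohort_sizes))]
    cohorts = [
        _simulate_cohort(sq, cfg, nm, n, drivers, gamma_truth)
        for sq, nm, n in zip(cohort_seqs, names, cfg.cohort_sizes)
    ]
    true_edges = {(tf, lnc) for tf, lncs in truth.items() for lnc in lncs}
    return SimulatedStudy(cohorts, truth, candidates, true_edges, gamma_truth, cfg)


def simulate_null_study(config: SimulationConfig) -> SimulatedStudy:
    """The same generative process with every planted effect forced to 0."""
    return simulate_study(replace(config, gamma=0.0))


def write_study(study: SimulatedStudy, outdir) -> None:
    """Write a study as the pipeline's standard on-disk formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for c in study.cohorts:
        write_expression(c.expression, out / f"{c.name}_expression.tsv")
        write_clinical(c.survival, out / f"{c.name}_clinical.tsv")
    write_gmt(study.candidates, out / "candidates.gmt", description="candidate")
    truth = pd.DataFrame(
        [
            (tf, lnc, study.gamma_truth.get(lnc, 0.0))
            for tf, lncs in study.network_truth.items()
            for lnc in lncs
        ],
        columns=["tf", "lnc", "gamma"],
    )
    truth.to_csv(out / "truth_edges.tsv", sep="\t", index=False)
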