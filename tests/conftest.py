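import numpy as np
import pandas as pd
import pytest

from lncrisk import CohortBundle, SimulationConfig, simulate_study


def make_bundle(expr_rows: dict, time, event, name="test", **covars) -> CohortBundle:
    """Build a small in-memory cohort from per-gene expression rows."""
    n = len(time)
    samples = [f"s{i + 1}" for i in range(n)]
    expr = pd.DataFrame(expr_rows, index=samples).T
    expr.columns = samples
    expr.index.name = "gene"
    surv = pd.DataFrame({"time": time, "event": event, **covars},
                        index=pd.Index(samples, name="sample"))
    return CohortBundle(expr, surv, name=name)


@pytest.fixture(scope="session")
def planted_study():
    """One planted-signal two-cohort study reused across read-only tests."""
    cfg = SimulationConfig(seed=11, cohort_sizes=(300, 200), n_lncrnas=200,
                           n_tfs=20, targets_per_tf=8, gamma=0.3)
    return simulate_study(cfg)
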