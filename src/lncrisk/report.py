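"""Plot-ready tables for survival curves and risk-score distributions."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import CohortBundle
from .risk import SignatureEvaluation

__all__ = ["km_plot_table", "risk_distribution_table"]


def km_plot_table(evaluation: SignatureEvaluation, bundle: CohortBundle) -> pd.DataFrame:
    """Long-format table to redraw the two-group KM plot.

    One row per (group, time) step plus one flagged row per censored sample
    (the '+' marks on a published curve), columns
    ``group, time, survival, censor_mark``.
    """
    time, event = bundle.time_event()
    groups = evaluation.assignment.group
    rows = []
    for label, km in (("high", evaluation.km_high), ("low", evaluation.km_low)):
        rows.append({"group": label, "time": 0.0, "survival": 1.0, "censor_mark": False})
        for t, s in zip(km.times, km.surv):
            rows.append({"group": label, "time": float(t), "survival": float(s),
                         "censor_mark": False})
        mask = (groups == label) & (event == 0)
        for t in np.sort(time[mask]):
            idx = np.searchsorted(km.times, t, side="right") - 1
            s = 1.0 if idx < 0 else float(km.surv[idx])
            rows.append({"group": label, "time": float(t), "survival": s,
                         "censor_mark": True})
    return pd.DataFrame(rows)


def risk_distribution_table(evaluation: SignatureEvaluation, bundle: CohortBundle) -> pd.DataFrame:
    """Per-sample table of median-centred scores, group and outcome, ordered
    by score — the usual risk-distribution strip under a KM figure."""
    a = evaluation.assignment
    time, event = bundle.time_event()
    med = float(np.median(a.scores))
    df = pd.DataFrame(
        {
            "sample": a.sample_ids,
            "score_minus_median": a.scores - med,
            "group": a.group,
            "time": time,
            "event": event,
        }
    )
    return df.sort_values("score_minus_median", kind="stable").reset_index(drop=True)
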