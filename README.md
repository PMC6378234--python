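# lncrisk

Ranking transcription factors (TFs) by the prognostic efficacy of their
long non-coding RNA (lncRNA) regulons in censored survival cohorts, with
ovarian serous carcinoma as the motivating setting.

Many TFs are poor prognostic markers through their own expression, yet the
panel of lncRNAs they regulate can carry a strong survival signal.
`lncrisk` implements that idea as a reusable pipeline for anyone with
gene-by-sample expression matrices, per-patient survival tables (OS, PFS
or DFS), and candidate TF→lncRNA binding sets:

1. **Regulon confirmation.** Candidate binding pairs (e.g. ChIP-seq
   derived, supplied as GMT) are kept when the TF and lncRNA are
   positively co-expressed: Pearson r > 0 with Benjamini–Hochberg
   FDR < 0.05 over all tested pairs.
2. **Risk-score model.** For a TF with regulon lnc₁…lncₙ, each member
   gets a coefficient βᵢ from a univariate Cox proportional-hazards fit,
   and each patient the score

   RiskScore = Σᵢ βᵢ · Exp(lncᵢ)

   Patients are split into high/low risk at the cohort's median score and
   the split is tested by the log-rank test; the continuous score is also
   reported as a hazard ratio per standard deviation.
3. **TF screen.** Every TF's regulon is scored and TFs are ranked by
   log-rank p-value, alongside the pre-model baseline (each TF's own
   expression in a univariate Cox fit).
4. **Validation & comparison.** Signatures are validated in independent
   cohorts by refitting or by z-score cut-point transfer, stratified by
   age/grade/stage/residual disease, adjusted for clinical covariates in
   a multivariate Cox model, compared against other markers by
   time-dependent ROC at the median survival time, and filtered for
   cross-cohort consistency of coefficient signs.

The survival machinery (Kaplan–Meier, log-rank, Cox with Efron ties,
BH-FDR, time-dependent ROC with optional IPCW) is implemented in-package
from first principles and cross-checked against independent
implementations in the test suite. A synthetic multi-cohort generator
with planted regulons and proportional-hazards survival makes every stage
testable without any data download.

## Worked example

`examples/01_screen_tfs.py` simulates a 399-patient cohort in which one
of 50 TFs truly drives hazard through its 10-lncRNA regulon
(+0.3 log-hazard per SD per member, ~50% censoring), confirms the
candidate network and ranks all TFs:

```
confirmed 507 of 1000 candidate edges across 50 TFs
   tf  n_targets  hr_per_sd  ci_low  ci_high   logrank_p        bh_q   baseline_p  rank
TF001         10       4.01    3.29     4.88   5.29e-30     2.64e-28     2.05e-17     1
TF021         10       1.75    1.52     2.03   2.16e-11     5.39e-10     3.06e-01     2
...
```

The planted TF001 ranks first: patients one standard deviation higher on
its regulon score die about 4× faster (HR/SD ≈ 4.0), and the median-split
log-rank p is vanishingly small. Note the null TFs also reach nominal
significance in-sample — the documented anti-conservatism of fitting and
evaluating on one cohort — while held-out evaluation is calibrated
(see `docs/methods.md`). The other example scripts walk through the
survival primitives, independent-cohort validation and stratification,
time-dependent ROC comparison, and risk-direction consistency filtering.

A `lncrisk` command-line interface exposes the same pipeline on files:
`simulate`, `network`, `screen`, `validate`, `stratify`, `roc`,
`consistency`, `report` (run `lncrisk --help`).

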