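"""The censored-survival building blocks on a hand-checkable dataset.

Kaplan-Meier curve, log-rank comparison, Cox proportional hazards and the
two-sample t-test, on inputs small enough to verify by hand.
"""

import numpy as np

from lncrisk import cox_fit, km_estimate, logrank_test, t_test

# six patients, months of follow-up; 0 = censored
time = np.array([5.0, 8.0, 12.0, 20.0, 30.0, 44.0])
event = np.array([1, 1, 0, 1, 1, 0])

km = km_estimate(time, event)
print("KM event times:", km.times, "\nKM survival:   ", km.surv.round(3),
      "\nmedian survival:", km.median_survival)

group = np.array(["hi", "hi", "hi", "lo", "lo", "lo"])
lr = logrank_test(time, event, group)
print(f"\nlog-rank chi2 = {lr.chi2:.3f}, p = {lr.p:.3f} "
      "(observed vs expected events between groups)")

x = np.array([0.9, 1.8, -0.3, 1.2, -0.8, -1.5])  # an expression covariate
fit = cox_fit(time, event, x, names=["expr"])
print(f"Cox beta = {fit.beta[0]:.3f}, HR = {fit.hr[0]:.2f} "
      f"(95% CI {fit.ci_low[0]:.2f}-{fit.ci_high[0]:.2f}), p = {fit.p[0]:.3f}")
print("HR > 1: each unit of expression multiplies the instantaneous "
      "death risk by that factor.")

t_stat, p = t_test([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
print(f"\nt-test: t = {t_stat:.3f}, p = {p:.3f} "
      "(pooled-variance two-sample comparison)")
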