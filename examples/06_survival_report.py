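"""Survival stratification metrics for a fitted risk model.

Kaplan–Meier curves per risk group, the log-rank test, and the
univariate Cox hazard ratio of high- vs low-risk membership.
"""

import numpy as np

import immunocontext as ic

rng = np.random.default_rng(8)
n = 120
high = rng.random(n) < 0.4
# high-risk group dies three times faster
times = np.where(high, rng.exponential(15.0, n), rng.exponential(45.0, n))
times = np.clip(times, 0.5, 113.0)
events = times < 113.0

km_low = ic.km_curve(times[~high], events[~high])
km_high = ic.km_curve(times[high], events[high])
print("5-year survival, low risk: ",
      round(float(km_low[km_low.time <= 60].survival.iloc[-1]), 2))
print("5-year survival, high risk:",
      round(float(km_high[km_high.time <= 60].survival.iloc[-1]), 2))

chi2, p = ic.logrank_test(times[~high], events[~high], times[high], events[high])
cox = ic.cox_hr_binary(times, events, high.astype(int))
print(f"log-rank χ² = {chi2:.1f}, p = {p:.2e}")
print(f"hazard ratio = {cox.hr:.2f} (95% CI {cox.ci_low:.2f}–{cox.ci_high:.2f})")
# HR ≈ 3 with a tight CI and a tiny p: the grouping separates survival
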