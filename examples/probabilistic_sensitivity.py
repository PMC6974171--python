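"""Probabilistic sensitivity analysis and the acceptability curve.

Samples every uncertain input simultaneously (beta event rates,
lognormal relative risks from their 95% CIs, gamma costs, truncated-
normal utilities drawn per arm), reruns the cohort model 10,000 times,
and reports how often each strategy has the highest net monetary
benefit across willingness-to-pay thresholds.
"""

import numpy as np

from achilles_cea import base_case_calibrated, ceac, run_psa

params = base_case_calibrated().params
result = run_psa(params, n=10_000, seed=1)

print("acceptability (fraction of draws won):")
print(result.acceptability.to_string(index=False))

curve = ceac(result, np.linspace(0, 150_000, 7))
print("\ncost-effectiveness acceptability curve:")
print(curve.to_string(index=False))

mean_dc = result.draws["delta_cost"].mean()
mean_dq = result.draws["delta_qalys"].mean()
print(f"\nmean incremental cost (operative - non-operative): ${mean_dc:,.0f}")
print(f"mean incremental QALYs: {mean_dq:+.3f}")
# The non-operative fraction is the probability that conservative care
# is the cost-effective choice given joint parameter uncertainty.
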