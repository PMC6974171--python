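"""Base-case cost-utility comparison of the two management strategies.

Builds the bundled base case (published event rates, episode costs and
utility schedule, with complication event costs calibrated against the
published strategy totals), runs the 2-year Markov cohort model for
both arms, and prints the incremental comparison.
"""

from achilles_cea import base_case_calibrated, compare, run_both

params = base_case_calibrated().params
outcomes = run_both(params)

print(f"{'strategy':<15}{'total cost ($)':>16}{'QALYs':>8}")
for strategy in ("non_operative", "operative"):
    o = outcomes[strategy]
    print(f"{strategy:<15}{o.total_cost:>16,.2f}{o.total_qalys:>8.2f}")

result = compare(outcomes["non_operative"], outcomes["operative"], (50_000.0,))
print(f"\nincremental cost (operative - non-operative): ${result.delta_cost:,.2f}")
print(f"incremental QALYs:                            {result.delta_qalys:+.3f}")
print(f"classification: {result.classification}")

# A positive incremental cost together with negative incremental QALYs
# means surgery is dominated: it costs more and delivers less quality-
# adjusted life, so no willingness-to-pay makes it the better buy.
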