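"""One-way threshold analysis: where does the preferred strategy flip?

Bisects three influential parameters on the calibrated base case.  Cost
parity (equal total expected costs) is the criterion for the two cost
parameters — with non-operative care both cheaper and more effective at
base case, surgery becomes the cost-effective choice exactly when it
stops being more expensive.  The quality-of-life threshold instead uses
the net-monetary-benefit flip at $50,000/QALY.
"""

from achilles_cea import base_case_calibrated, find_threshold

params = base_case_calibrated().params

hosp = find_threshold(
    "episode_costs.operative.hospitalization", (0.0, 6000.0), params,
    criterion="cost_parity",
)
print(f"operative hospitalization cost: surgery preferred below "
      f"${hosp.threshold_value:,.2f} (base case $3,145)")

wage = find_threshold(
    "wage.hourly_wage", (1.0, 100.0), params, criterion="cost_parity"
)
print(f"hourly wage: surgery preferred above ${wage.threshold_value:,.2f}/h "
      f"(base case $24.48/h)")

qol = find_threshold(
    "nonoperative_utility_penalty", (0.0, 0.2), params,
    wtp=50_000.0, criterion="nmb_flip",
)
print(f"non-operative quality-of-life decrement: surgery preferred beyond "
      f"{100 * qol.threshold_value:.2f}% (base case 0%)")

# Each threshold says how far one assumption must move, all else fixed,
# before operative management becomes the cost-effective strategy.
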