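# achilles-cea

A Markov cohort cost-utility model comparing **operative** versus
**non-operative** management of acute Achilles tendon rupture (both
with accelerated functional rehabilitation), from the societal
perspective, over a 2-year horizon of eight 3-month cycles.

The package is for health-economics and orthopaedics researchers who
want a tested, fully reproducible re-implementation of this published
decision model: every input is generated in code from the published
tables, every assumption is a documented, switchable parameter, and the
whole analysis — base case, calibration, threshold search,
probabilistic sensitivity analysis — runs in seconds on one CPU with no
external data.

## The model

A cohort enters treatment in cycle 1 and incurs that episode's cost
(hospitalization, surgeon, physical therapy, and indirect cost of
missed work). At the end of the first post-treatment cycle the episode
resolves into one of four health states: full benefit, minor
complication, major complication, or re-rupture. Re-ruptures are always
revised surgically — the revision restarts the recovery clock and
re-enters the event lottery with operative transition probabilities.
Utilities are time-dependent (0.7 for the first cycle after any
treatment, 0.8 for the second, 0.9 thereafter), with minor/major
complications multiplying utility by 0.9/0.8 to the horizon. Costs and
quality-adjusted life years accrue per cycle of occupancy
(QALY = Σ occupancy × utility × cycle length); nothing is discounted
over the short horizon.

Strategies are compared by the incremental cost-effectiveness ratio
ICER = ΔC/ΔE with dominance classification, and by net monetary
benefit NMB(λ) = λ·E − C at willingness-to-pay λ ($50,000 and
$100,000/QALY). One-way sensitivity analysis bisects for decision
thresholds; probabilistic sensitivity analysis samples all inputs
jointly (beta event rates, lognormal relative risks from their 95% CIs,
gamma costs, truncated-normal utilities) and summarizes acceptability
over λ.

The per-event costs of major and minor complications are not printed in
the source; the package solves for the pair that reproduces the
published strategy totals (total cost is affine in the two unknowns, so
this is an exact 2×2 linear solve). The solved minor-complication cost
is negative, which the package reports as a structural diagnostic — see
`docs/methods.md`.

## Worked example

```python
from achilles_cea import base_case_calibrated, compare, run_both

params = base_case_calibrated().params
outcomes = run_both(params)
result = compare(outcomes["non_operative"], outcomes["operative"], (50_000.0,))
```

Running `python examples/base_case.py` prints:

```
strategy         total cost ($)   QALYs
non_operative         13,413.04    1.70
operative             13,936.38    1.68

incremental cost (operative - non-operative): $523.34
incremental QALYs:                            -0.020
classification: reference_dominates
```

Surgery costs $523.34 more over two years (the higher hospitalization
cost is mostly, but not fully, offset by 2.5 fewer weeks of missed
work) and yields 0.02 fewer QALYs (its lower re-rupture rate does not
compensate for its higher complication rates), so non-operative care
*dominates*: no willingness-to-pay threshold makes surgery the better
buy at base case.

`examples/threshold_analysis.py` shows how far single assumptions must
move before surgery becomes cost-effective — operative hospitalization
cost below $2,621.66, hourly wage above $28.87, or non-operative
quality of life 1.76% below operative. `examples/probabilistic_sensitivity.py`
runs the 10,000-draw PSA (non-operative care wins ≈66% of draws at
$50,000/QALY under the documented default spreads).

A thin CLI wraps the same library calls:

```sh
achilles-cea base-case
achilles-cea dsa --param episode_costs.operative.hospitalization --low 0 --high 6000
achilles-cea psa --iterations 10000 --seed 1 --out-dir out/
achilles-cea dump-fixture base_case --out base_case.yaml
```

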