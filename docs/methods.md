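# Methods

## Model structure

The model is a deterministic Markov cohort simulation over an expanded
state space. Eight 3-month cycles cover a 2-year horizon. The cohort
enters treatment (operative or non-operative, both with accelerated
functional rehabilitation) at the start of cycle 1 and incurs the full
episode cost — hospitalization, surgeon fee, physical therapy, and the
indirect cost of missed work — in that cycle.

Episode resolution happens at the end of the first post-treatment
cycle: the treated mass splits into full benefit, minor complication,
major complication, and re-rupture according to the per-episode event
probabilities. The states carried from cycle to cycle are the pathway
(in recovery, full benefit, minor complication, major complication,
re-rupture pending resolution) crossed with the recovery clock — the
number of cycles since the most recent treatment — which saturates once
the utility schedule becomes flat, keeping the state space small
(ten states in the default configuration).

Re-ruptured mass undergoes revision surgery at the start of the next
cycle: it incurs the re-rupture episode cost (including its own 8 weeks
of missed work), restarts the recovery clock, and re-enters the event
lottery one cycle later with *operative* transition probabilities,
because re-ruptures are treated surgically regardless of the initial
strategy. This recursion is truncated only by the horizon; a re-rupture
occurring at the end of the final cycle remains "pending" in the
post-horizon snapshot and generates no further cost or utility.

Expected QALYs accrue as occupancy × utility × cycle length each
cycle. Utility is time-dependent — 0.7 during the first cycle after any
treatment, 0.8 during the second, 0.9 thereafter — and complication
pathways multiply the scheduled utility by 0.9 (minor) or 0.8 (major).
There is no mortality state, no half-cycle correction, and no
discounting in the base case (a discount rate field exists and defaults
to zero).

### Assumptions where the source was silent

These choices are exposed as configuration and kept separate from the
published inputs:

- **Complication timing and duration.** Complications resolve at the
  end of the treatment cycle (same timing as re-ruptures, chosen for
  symmetry), and their utility decrements persist to the horizon by
  default. A `decrement_duration="single_cycle"` switch restricts the
  decrement to the first post-resolution cycle. The persistent default
  back-calculates to within 0.02 QALYs of the published per-strategy
  totals (we obtain 1.70/1.68 against published 1.69/1.67).
- **Complication event costs** are charged once, at the cycle of
  resolution.
- **Missed work** is charged once per treatment episode, in the
  episode's first cycle; re-rupture surgery adds its own 8 weeks on top
  of the initial episode's allocation.
- **Re-rupture surgeon fee** reuses the primary operative fee ($810),
  as the published cost table prints the same figure in both columns.

## Inputs

All monetary values are 2014 US dollars, held as floats at full
precision and rounded only for display (calibration and bisection need
continuous arithmetic; the sub-cent precision is immaterial at
reporting time).

- Non-operative per-episode event probabilities: re-rupture 9.6%,
  major complication 3.1%, minor complication 4.3%.
- Operative probabilities: 3.8% / 5.5% / 15.4%, taken verbatim from the
  published table. They can alternatively be derived as relative risk ×
  non-operative rate (RR 0.40, 1.79, 3.54); the two routes disagree
  slightly (3.54 × 4.3% = 15.22% ≠ 15.4%) because the published columns
  are themselves not perfectly consistent, and the verbatim column is
  the default because those are the published operative inputs.
- Episode costs (operative / non-operative / re-rupture surgery):
  hospitalization 3145 (95% CI 3045–3244) / 0 / 3944; surgeon 810 /
  283 / 810; physical therapy 821 in all arms; missed work 8 / 10.5 / 8
  weeks at 40 h/week.
- The hourly wage defaults to $7834 / (8 × 40) = $24.48125 — the value
  implied exactly by the printed missed-work costs — rather than the
  rounded "$24/h" of the source text, so the cost table reproduces to
  within $1.
- Utility schedule (0.7, 0.8, 0.9), full-benefit utility 0.9,
  complication decrement multipliers 0.9 (minor) and 0.8 (major).
- Run settings: 8 cycles × 0.25 years, WTP grid {50,000; 100,000},
  10,000 PSA iterations.

## Calibration of complication event costs

The per-event costs of major and minor complications were sourced by
the original authors from literature not reproduced in print. Because
total expected cost is affine in these two unknowns, the pair
reproducing both published strategy totals ($13,936.38 operative,
$13,413.04 non-operative) solves a 2×2 linear system whose coefficients
are measured by running the engine at unit prices.

The solution is **major ≈ +$25,463, minor ≈ −$4,117**. The negative
component is structural, not numerical: after re-rupture follow-on
episodes are accounted, the operative arm has 1.57× the major-
complication incidence and 2.74× the minor-complication incidence of
the non-operative arm, so any non-negative price pair forces the
operative arm's complication spending to exceed the non-operative
arm's by at least a factor 1.57 — but the published totals leave a gap
ratio of only ≈1.16. No non-negative decomposition exists under this
structure; the authors' model must have differed in some unreported
respect (e.g., complication costs that interact with episode costs, or
per-cycle rather than per-event charging).

The calibration API therefore refuses a negative solution by default
(raising `CalibrationError` rather than clipping), and the calibrated
base case used for threshold analysis opts in explicitly with
`allow_negative=True`, reporting the solved pair as a diagnostic. For
the threshold and PSA analyses this is benign: the calibrated model
reproduces the published totals, incremental cost, and dominance
verdict exactly, which is all those analyses consume.

## Decision metrics

ICERs are reported only for genuine trade-offs; under dominance the
classification label is reported instead of a negative ratio. NMB ties
(|difference| < 1e−9) resolve to the reference (non-operative)
strategy — the less invasive option; the tie-break is arbitrary and
documented. Only two strategies exist, so extended dominance does not
arise.

## Threshold analysis

Thresholds are found by bisection to an absolute tolerance of $0.01 for
monetary parameters and 1e−4 for probabilities and utilities, then
verified by evaluation on both flanks. Two criteria are implemented:

- `cost_parity` (default): the strategies' total expected costs cross.
  With non-operative care both cheaper and more effective at base case,
  this is the exact point at which surgery stops being dominated on
  cost, and it reproduces the published flip points: operative
  hospitalization $2,621.66 (= 3145 − 523.34) and hourly wage $28.87
  (rounds to $29).
- `nmb_flip`: the NMB difference at a given willingness-to-pay changes
  sign. Used for the quality-of-life threshold: a proportional
  decrement of 1.76% (rounds to 2%) on all non-operative utilities
  makes surgery preferred at $50,000/QALY. (Under ΔQ = −0.02 an NMB
  flip on hospitalization cost would instead occur near $1,622, which
  is not what the source prints — its cost thresholds behave as cost
  parity.)

Sweeping the non-operative missed-work weeks to cost parity gives
11.03 weeks, i.e. 3.03 weeks more than the operative 8 (the source
prints 3.3; the printed incremental cost of $523.34 at the implied wage
corresponds to 523.34 / (40 × 24.48) ≈ 0.53 weeks above the base-case
2.5-week difference, so 3.0 is the arithmetically consistent value).

The tornado ranking evaluates the NMB difference at the endpoints of
each parameter's plausible range (printed CIs where available, ±20%
otherwise) and sorts by interval width. With the calibrated (extreme)
major-complication price, the operative major-complication rate swept
over its relative-risk CI produces the widest bar, ahead of the
relative-utility and hospitalization-cost bars; rankings are sensitive
to both the chosen ranges and the unpublished complication prices, so
they should be read qualitatively.

## Probabilistic sensitivity analysis

Each of 10,000 iterations samples every uncertain parameter
simultaneously and reruns both arms. Families follow parameter roles:

- **beta** for the three non-operative event probabilities
  (method-of-moments from mean and SE);
- **lognormal** for the three relative risks, with log-mean ln(point)
  and log-SD (ln CI_high − ln CI_low)/3.92;
- **gamma** for costs (hospitalization SE from its printed CI,
  (3244 − 3045)/3.92 ≈ 50.8; other costs and the hourly wage SE = 10%
  of the mean; the wage draw propagates into all missed-work
  components);
- **truncated normal** on [0, 1] with SD 0.05 for utilities.

Operative event rates are re-derived per draw as sampled RR × sampled
non-operative rate (clipped to [0, 1]; the rare draw exhausting the
probability simplex is rescaled proportionally to sum 0.999), so rate
and relative-risk uncertainty propagate coherently. Sampled utility
schedules are made non-decreasing by a running maximum. The calibrated
major-complication cost is gamma-sampled like other costs; the negative
minor-complication diagnostic value has no gamma representation and is
held fixed.

Utility schedules are drawn **separately for each arm** (complication
decrements shared). The deterministic analysis treats non-operative
quality of life as a parameter in its own right — the strategy choice
flips when it falls 2% below operative — so the sampling plan must
allow relative utilities to vary; with a single shared schedule the
acceptability curve degenerates toward certainty (≈93% at $50,000/QALY)
because the dominant uncertainty is frozen out.

All draws come from one seeded `numpy` generator, consumed one vector
per parameter in a fixed documented order (the spec echo in every PSA
result and manifest), making runs bit-for-bit reproducible. With these
defaults, non-operative management is cost-effective in ≈66% of draws
at $50,000/QALY and ≈65% at $100,000/QALY (published: 71.7% and
69.1% — the authors' spread parameters were not published, so only the
direction and rough magnitude are reproducible; note both analyses
agree that acceptability *falls* as willingness-to-pay rises, because
surgery's deficit is in effectiveness, not cost).

## Synthetic scenarios and what the tests show

The scenario generator produces (i) the published base case, in code so
it cannot drift; (ii) random valid parameter sets (event triples
summing below 0.9, costs up to $50,000, utilities in (0.3, 1]) used to
fuzz mass conservation across 1,000 seeds; and (iii) degenerate
scenarios with closed-form outcomes — zero events (QALYs exactly
0.25 × (0.7 + 0.8 + 6×0.9) = 1.725, cost equal to the episode total),
identical arms (exact equivalence), and certain re-rupture (seven
revision surgeries, utility 0.7 throughout). An exhaustive
branch-enumeration oracle checks the engine to 1e−9 on short-horizon
instances where every pathway can be enumerated.

These tests validate the *arithmetic* of the model, not its clinical
fidelity: the cohort is homogeneous, event probabilities are constant
per episode, complications neither resolve nor recur, and nobody dies.
Conclusions about real patients inherit all the limitations of the
published inputs.

## Known limitations

- The calibrated complication costs are a reproduction device, not
  literature values; analyses that depend on the *level* (not the
  total) of complication spending — notably the tornado ranking —
  inherit their distortion.
- The published QALY totals (1.69/1.67) are matched to within 0.02 but
  not exactly; the residual reflects unreported structural details
  (complication duration, cycle timing).
- PSA acceptability depends on assumed spreads; the defaults are
  documented and overridable, and results are reported with that
  caveat.
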