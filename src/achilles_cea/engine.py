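"""Markov cohort engine for the two-year Achilles-rupture model.

The cohort enters treatment (operative or non-operative) in the first
3-month cycle and accrues that episode's full cost, including missed
work.  At the end of the first post-treatment cycle the episode
resolves: the cohort splits into full benefit, minor complication,
major complication, or re-rupture.  Re-ruptured mass undergoes revision
surgery at the start of the next cycle — incurring the re-rupture
episode cost, restarting the recovery utility clock, and re-entering
the event lottery one cycle later with *operative* transition
probabilities, since re-ruptures are always treated surgically.
Complication pathways persist to the horizon (by default) with their
multiplicative utility decrements; complication event costs are charged
once, at resolution.

Quality-adjusted life years accrue each cycle as occupancy x utility x
cycle length, with the utility taken from the time-since-treatment
schedule (0.7 in the first cycle after a treatment, 0.8 in the second,
0.9 thereafter in the base case).  There is no half-cycle correction,
no mortality, and no discounting in the base case (the settings carry a
discount rate for completeness; it defaults to zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .parameters import EventRates, ParameterSet, episode_cost_total

Strategy = Literal["operative", "non_operative"]

STRATEGIES: tuple[Strategy, ...] = ("operative", "non_operative")

# Pathways of the expanded state space.  The recovery clock (cycles since
# the most recent treatment) is tracked alongside; it saturates once the
# utility schedule becomes flat.
_PATHWAYS = ("in_recovery", "full_benefit", "minor_complication",
             "major_complication", "rerupture_pending_resolution")


class InternalConsistencyError(RuntimeError):
    """Cohort mass was not conserved during a run."""


def resolve_episode(rates: EventRates) -> dict[str, float]:
    """Outcome distribution of one treatment episode.

    Returns probabilities for ``full_benefit``, ``minor``, ``major`` and
    ``rerupture``; they sum to one exactly (full benefit is the
    complement of the three event probabilities).
    """
    p_events = rates.p_rerupture + rates.p_major + rates.p_minor
    return {
        "full_benefit": 1.0 - p_events,
        "minor": rates.p_minor,
        "major": rates.p_major,
        "rerupture": rates.p_rerupture,
    }


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle occupancy and accruals of one strategy run.

    ``occupancy`` has ``n_cycles + 1`` rows: row 0 is the cohort during
    the first cycle (everyone freshly treated, in recovery); row c for
    c >= 1 is the distribution after the end-of-cycle-c transition,
    i.e. the cohort during cycle c + 1 (row ``n_cycles`` is the
    post-horizon snapshot, where still-unresolved re-ruptures remain
    pending).  ``cost_accrual[c]`` and ``qaly_accrual[c]`` are the
    amounts accrued during cycle c (index 0 unused).
    """

    states: tuple[str, ...]
    occupancy: np.ndarray
    cost_accrual: np.ndarray
    qaly_accrual: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per cycle per occupied state."""
        rows = []
        n_cycles = len(self.cost_accrual) - 1
        for c in range(self.occupancy.shape[0]):
            cycle_cost = self.cost_accrual[c] if c <= n_cycles else 0.0
            cycle_q = self.qaly_accrual[c] if c <= n_cycles else 0.0
            for s, label in enumerate(self.states):
                rows.append(
                    {
                        "cycle": c,
                        "state": label,
                        "occupancy": self.occupancy[c, s],
                        "cycle_cost": cycle_cost,
                        "cycle_qalys": cycle_q,
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path: str) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class StrategyOutcome:
    """Expected totals for one strategy over the model horizon."""

    strategy: Strategy
    total_cost: float
    total_qalys: float
    trace: CohortTrace


def run_cohort(strategy: Strategy, params: ParameterSet) -> StrategyOutcome:
    """Run the cohort model for one strategy and accrue expected totals."""
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")

    settings = params.settings
    n = settings.n_cycles
    dt = settings.cycle_length
    util = params.utilities
    if strategy == "non_operative" and params.utilities_nonoperative is not None:
        util = params.utilities_nonoperative

    initial_rates = (
        params.rates_operative
        if strategy == "operative"
        else params.rates_nonoperative
    )
    followon_rates = params.rates_operative  # re-ruptures are treated surgically
    initial_kind = "operative" if strategy == "operative" else "non_operative"
    initial_episode = episode_cost_total(params.episode_costs[initial_kind])
    rerupture_episode = episode_cost_total(params.episode_costs["rerupture_surgery"])
    c_major = params.complication_costs.major_cost
    c_minor = params.complication_costs.minor_cost

    # Proportional quality-of-life penalty on the non-operative arm,
    # swept by the deterministic sensitivity analysis.
    u_scale = (
        1.0 - params.nonoperative_utility_penalty
        if strategy == "non_operative"
        else 1.0
    )

    # Recovery clock saturates once the schedule is flat; keep >= 3 so
    # the first two post-resolution cycles stay distinguishable.
    k_max = max(3, len(util.recovery_utilities))
    single_cycle = util.decrement_duration == "single_cycle"

    def state_utility(pathway: str, k: int) -> float:
        base = util.utility(k)
        if pathway == "minor_complication":
            mult = util.minor_multiplier if (not single_cycle or k == 2) else 1.0
        elif pathway == "major_complication":
            mult = util.major_multiplier if (not single_cycle or k == 2) else 1.0
        else:
            mult = 1.0
        return base * mult

    state_labels: list[str] = ["in_recovery"]
    for pathway in ("full_benefit", "minor_complication", "major_complication"):
        for k in range(2, k_max + 1):
            state_labels.append(f"{pathway}@{k}")
    state_labels.append("rerupture_pending_resolution")
    index = {label: i for i, label in enumerate(state_labels)}

    occupancy = np.zeros((n + 1, len(state_labels)))
    cost_accrual = np.zeros(n + 1)
    qaly_accrual = np.zeros(n + 1)

    # Occupancy during the current cycle, keyed by state label.
    current: dict[str, float] = {label: 0.0 for label in state_labels}
    current["in_recovery"] = 1.0
    occupancy[0] = [current[label] for label in state_labels]

    r = settings.discount_rate
    for cycle in range(1, n + 1):
        disc = 1.0 / (1.0 + r) ** ((cycle - 1) * dt) if r else 1.0
        rates = initial_rates if cycle == 1 else followon_rates
        dist = resolve_episode(rates)

        # Episode cost of the treatment delivered at the start of this cycle.
        if cycle == 1:
            cost_accrual[cycle] += disc * initial_episode
        # (re-rupture surgery costs are added below, when pending mass
        #  converts to recovery at the start of the next cycle)

        # Utility accrual for this cycle's occupancy.
        q = current["in_recovery"] * state_utility("in_recovery", 1)
        for pathway in ("full_benefit", "minor_complication", "major_complication"):
            for k in range(2, k_max + 1):
                q += current[f"{pathway}@{k}"] * state_utility(pathway, k)
        qaly_accrual[cycle] = disc * q * dt * u_scale

        # End-of-cycle transition.
        nxt = {label: 0.0 for label in state_labels}
        m = current["in_recovery"]
        nxt["full_benefit@2"] += m * dist["full_benefit"]
        nxt["minor_complication@2"] += m * dist["minor"]
        nxt["major_complication@2"] += m * dist["major"]
        nxt["rerupture_pending_resolution"] += m * dist["rerupture"]
        # Complication event costs are charged once, at resolution.
        cost_accrual[cycle] += disc * m * (
            dist["major"] * c_major + dist["minor"] * c_minor
        )
        for pathway in ("full_benefit", "minor_complication", "major_complication"):
            for k in range(2, k_max + 1):
                k_next = min(k + 1, k_max)
                nxt[f"{pathway}@{k_next}"] += current[f"{pathway}@{k}"]

        # Pending re-ruptures undergo surgery at the start of the next
        # cycle (inside the horizon only) and restart the recovery clock.
        if cycle < n:
            pending = nxt["rerupture_pending_resolution"]
            if pending:
                disc_next = 1.0 / (1.0 + r) ** (cycle * dt) if r else 1.0
                cost_accrual[cycle + 1] += disc_next * pending * rerupture_episode
                nxt["in_recovery"] += pending
                nxt["rerupture_pending_resolution"] = 0.0

        total_mass = sum(nxt.values())
        if abs(total_mass - 1.0) > 1e-9:
            raise InternalConsistencyError(
                f"cohort mass {total_mass!r} after cycle {cycle} deviates from 1"
            )
        current = nxt
        occupancy[cycle] = [current[label] for label in state_labels]

    trace = CohortTrace(
        states=tuple(state_labels),
        occupancy=occupancy,
        cost_accrual=cost_accrual,
        qaly_accrual=qaly_accrual,
    )
    return StrategyOutcome(
        strategy=strategy,
        total_cost=float(cost_accrual.sum()),
        total_qalys=float(qaly_accrual.sum()),
        trace=trace,
    )


def run_both(params: ParameterSet) -> dict[Strategy, StrategyOutcome]:
    """Convenience: run the cohort under both strategies."""
    return {s: run_cohort(s, params) for s in STRATEGIES}


def expected_rerupture_mass(params: ParameterSet, strategy: Strategy) -> float:
    """Fraction of the cohort that ever re-ruptures within the horizon.

    Equals the initial re-rupture probability times a truncated geometric
    series in the post-surgical re-rupture probability, because every
    re-rupture is revised surgically and can re-rupture again each
    subsequent cycle until the horizon.
    """
    n = params.settings.n_cycles
    q0 = (
        params.rates_operative.p_rerupture
        if strategy == "operative"
        else params.rates_nonoperative.p_rerupture
    )
    p = params.rates_operative.p_rerupture
    total = 0.0
    treated = 1.0  # mass entering a treatment episode this cycle
    for cycle in range(1, n + 1):
        p_re = q0 if cycle == 1 else p
        ruptured = treated * p_re
        total += ruptured
        treated = ruptured  # re-treated at the start of the next cycle
    return total
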