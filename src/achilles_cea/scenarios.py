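"""Bundled and synthetic scenarios for the cost-utility model.

The published base case is generated in code, field for field, so it
cannot drift from the source tables; random valid parameter sets feed
the property-test suite; and a handful of degenerate scenarios carry
closed-form expected outcomes used as exact oracles for the engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .parameters import (
    ComplicationEventCosts,
    EpisodeCosts,
    EventRates,
    ParameterSet,
    RelativeRisk,
    RunSettings,
    UtilitySchedule,
    WageModel,
    calibrate_complication_costs,
    missed_work_cost,
    set_param,
)

# Published base-case totals (2014 USD) used as calibration targets for
# the unpublished per-event complication costs.
BASE_CASE_TOTAL_OPERATIVE = 13_936.38
BASE_CASE_TOTAL_NONOPERATIVE = 13_413.04

# Hourly wage implied exactly by the printed missed-work costs
# ($7834 over 8 weeks at 40 h/week); the source text rounds it to $24/h.
BASE_CASE_HOURLY_WAGE = 7834.0 / (8 * 40)


@dataclass(frozen=True)
class ScenarioFixture:
    """A named parameter set, optionally with closed-form expectations.

    ``expected`` maps strategy name to ``{"total_cost": ..,
    "total_qalys": ..}`` where those are analytically known.
    """

    name: str
    params: ParameterSet
    expected: Optional[dict[str, dict[str, float]]] = None


def base_case_fixture() -> ScenarioFixture:
    """The published base case, complication event costs left at zero.

    Event rates and relative risks follow the source meta-analysis;
    episode costs rebuild the published cost table; utilities follow the
    time-dependent schedule with 10%/20% minor/major decrements.  The
    per-event complication costs were sourced from literature not
    reproduced in print, so they default to zero here — see
    :func:`base_case_calibrated` for the pair solved against the
    published strategy totals.
    """
    wage = WageModel(hourly_wage=BASE_CASE_HOURLY_WAGE)
    params = ParameterSet(
        rates_nonoperative=EventRates(p_rerupture=0.096, p_major=0.031, p_minor=0.043),
        rates_operative=EventRates(p_rerupture=0.038, p_major=0.055, p_minor=0.154),
        relative_risks={
            "rerupture": RelativeRisk(
                event="rerupture", point=0.40, ci_low=0.12, ci_high=1.32
            ),
            "major_complication": RelativeRisk(
                event="major_complication", point=1.79, ci_low=0.64, ci_high=5.01
            ),
            "minor_complication": RelativeRisk(
                event="minor_complication", point=3.54, ci_low=0.40, ci_high=31.61
            ),
        },
        episode_costs={
            "operative": EpisodeCosts(
                kind="operative",
                hospitalization=3145.0,
                hospitalization_ci=(3045.0, 3244.0),
                surgeon=810.0,
                physical_therapy=821.0,
                missed_work=missed_work_cost(8.0, wage),
            ),
            "non_operative": EpisodeCosts(
                kind="non_operative",
                hospitalization=0.0,
                surgeon=283.0,
                physical_therapy=821.0,
                missed_work=missed_work_cost(10.5, wage),
            ),
            "rerupture_surgery": EpisodeCosts(
                kind="rerupture_surgery",
                hospitalization=3944.0,
                surgeon=810.0,
                physical_therapy=821.0,
                missed_work=missed_work_cost(8.0, wage),
            ),
        },
        complication_costs=ComplicationEventCosts(major_cost=0.0, minor_cost=0.0),
        wage=wage,
        utilities=UtilitySchedule(),
        settings=RunSettings(),
    )
    return ScenarioFixture(name="base_case", params=params)


def base_case_calibrated() -> ScenarioFixture:
    """Base case with complication event costs solved against the
    published strategy totals.

    The solved pair reproduces both totals to the cent by construction.
    Under this model structure the algebraic solution carries a negative
    minor-complication cost — a structural-assumption mismatch flag, not
    a literature value — so it is requested with ``allow_negative`` and
    reported as such wherever it is used.
    """
    base = base_case_fixture()
    costs = calibrate_complication_costs(
        base.params,
        BASE_CASE_TOTAL_OPERATIVE,
        BASE_CASE_TOTAL_NONOPERATIVE,
        allow_negative=True,
    )
    params = set_param(base.params, "complication_costs", costs)
    return ScenarioFixture(name="base_case_calibrated", params=params)


def random_scenario(
    rng: np.random.Generator, n_cycles: int = 8
) -> ScenarioFixture:
    """A random valid parameter set for property testing.

    Event-probability triples are drawn with sum < 0.9, cost components
    in (0, 50,000], utilities in (0.3, 1] (sorted non-decreasing), weeks
    of missed work in [0, 26].  Deterministic given the generator state.
    """

    def rates() -> EventRates:
        while True:
            p = rng.uniform(0, 0.6, size=3)
            if p.sum() < 0.9:
                return EventRates(p_rerupture=p[0], p_major=p[1], p_minor=p[2])

    def rr(event: str) -> RelativeRisk:
        lo = rng.uniform(0.05, 1.0)
        hi = lo * rng.uniform(1.0, 20.0)
        point = float(np.sqrt(lo * hi))
        return RelativeRisk(event=event, point=point, ci_low=lo, ci_high=hi)

    wage = WageModel(
        hourly_wage=rng.uniform(1.0, 100.0),
        weeks_missed={
            "operative": rng.uniform(0, 26),
            "non_operative": rng.uniform(0, 26),
            "rerupture_surgery": rng.uniform(0, 26),
        },
    )

    def episode(kind: str) -> EpisodeCosts:
        return EpisodeCosts(
            kind=kind,
            hospitalization=0.0 if kind == "non_operative" else rng.uniform(0, 50_000),
            surgeon=rng.uniform(0, 5_000),
            physical_therapy=rng.uniform(0, 5_000),
            missed_work=missed_work_cost(wage.weeks_missed[kind], wage),
        )

    u = np.sort(rng.uniform(0.3, 1.0, size=3))
    params = ParameterSet(
        rates_nonoperative=rates(),
        rates_operative=rates(),
        relative_risks={
            "rerupture": rr("rerupture"),
            "major_complication": rr("major_complication"),
            "minor_complication": rr("minor_complication"),
        },
        episode_costs={k: episode(k) for k in
                       ("operative", "non_operative", "rerupture_surgery")},
        complication_costs=ComplicationEventCosts(
            major_cost=rng.uniform(0, 50_000), minor_cost=rng.uniform(0, 50_000)
        ),
        wage=wage,
        utilities=UtilitySchedule(
            recovery_utilities=tuple(float(x) for x in u),
            full_benefit_utility=float(u[-1]),
            minor_multiplier=rng.uniform(0.5, 1.0),
            major_multiplier=rng.uniform(0.5, 1.0),
        ),
        settings=RunSettings(
            n_cycles=n_cycles, cycle_length=0.25, horizon=0.25 * n_cycles
        ),
    )
    return ScenarioFixture(name="random", params=params)


def degenerate_scenarios() -> list[ScenarioFixture]:
    """Scenarios with hand-computable outcomes, used as exact oracles."""
    base = base_case_fixture().params
    out: list[ScenarioFixture] = []

    # No adverse events: each arm accrues its episode cost once and the
    # undiscounted utility schedule 0.25 * (0.7 + 0.8 + 6 * 0.9) = 1.725.
    zero = EventRates(p_rerupture=0.0, p_major=0.0, p_minor=0.0)
    params = set_param(base, "rates_nonoperative", zero)
    params = set_param(params, "rates_operative", zero)
    sched = params.utilities
    dt = params.settings.cycle_length
    q_clean = dt * sum(
        sched.utility(k) for k in range(1, params.settings.n_cycles + 1)
    )
    out.append(
        ScenarioFixture(
            name="zero_events",
            params=params,
            expected={
                "operative": {
                    "total_cost": 3145.0 + 810.0 + 821.0 + 7834.0,
                    "total_qalys": q_clean,
                },
                "non_operative": {
                    "total_cost": 283.0 + 821.0 + missed_work_cost(10.5, base.wage),
                    "total_qalys": q_clean,
                },
            },
        )
    )

    # Identical arms: zero increments, comparison must report equivalence.
    params = set_param(base, "rates_operative", base.rates_nonoperative)
    op_as_nonop = EpisodeCosts(
        kind="operative",
        hospitalization=0.0,
        surgeon=base.episode_costs["non_operative"].surgeon,
        physical_therapy=base.episode_costs["non_operative"].physical_therapy,
        missed_work=base.episode_costs["non_operative"].missed_work,
    )
    params = set_param(params, "episode_costs.operative", op_as_nonop)
    out.append(ScenarioFixture(name="equal_arms", params=params, expected=None))

    # Certain re-rupture: every episode re-ruptures, so the cohort is in
    # recovery (utility 0.7) in all 8 cycles and undergoes 7 revision
    # surgeries after the initial treatment.
    certain = EventRates(p_rerupture=1.0, p_major=0.0, p_minor=0.0)
    params = set_param(base, "rates_nonoperative", certain)
    params = set_param(params, "rates_operative", certain)
    n = params.settings.n_cycles
    rerup_total = 3944.0 + 810.0 + 821.0 + 7834.0
    q_recovery = dt * sched.utility(1) * n
    out.append(
        ScenarioFixture(
            name="certain_rerupture",
            params=params,
            expected={
                "operative": {
                    "total_cost": (3145.0 + 810.0 + 821.0 + 7834.0)
                    + (n - 1) * rerup_total,
                    "total_qalys": q_recovery,
                },
                "non_operative": {
                    "total_cost": (283.0 + 821.0 + missed_work_cost(10.5, base.wage))
                    + (n - 1) * rerup_total,
                    "total_qalys": q_recovery,
                },
            },
        )
    )
    return out


_NAMED = {
    "base_case": base_case_fixture,
    "base_case_calibrated": base_case_calibrated,
}


def named_fixture(name: str) -> ScenarioFixture:
    """Look up a scenario by name (degenerate scenarios included)."""
    if name in _NAMED:
        return _NAMED[name]()
    for fixture in degenerate_scenarios():
        if fixture.name == name:
            return fixture
    raise KeyError(f"unknown fixture {name!r}")
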