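import numpy as np
import pytest

from achilles_cea import (
    ParameterSet,
    base_case_calibrated,
    base_case_fixture,
    random_scenario,
    run_cohort,
)
from achilles_cea.parameters import episode_cost_total


@pytest.fixture(scope="session")
def base_params() -> ParameterSet:
    return base_case_fixture().params


@pytest.fixture(scope="session")
def calibrated_params() -> ParameterSet:
    return base_case_calibrated().params


def enumerate_expected(strategy: str, params: ParameterSet) -> tuple[float, float]:
    """Exhaustive branch enumeration of the episode/outcome tree.

    Independent oracle for the cohort engine: walks every treatment
    pathway explicitly (initial episode, then re-rupture surgeries in
    subsequent cycles), multiplying branch probabilities, and sums
    expected cost and QALYs.  Exact for any horizon, but exponential in
    the number of treatment generations — use on short horizons.
    """
    n = params.settings.n_cycles
    dt = params.settings.cycle_length
    util = params.utilities
    if strategy == "non_operative" and params.utilities_nonoperative is not None:
        util = params.utilities_nonoperative
    u_scale = (
        1.0 - params.nonoperative_utility_penalty
        if strategy == "non_operative"
        else 1.0
    )
    kind = "operative" if strategy == "operative" else "non_operative"
    initial_cost = episode_cost_total(params.episode_costs[kind])
    rerup_cost = episode_cost_total(params.episode_costs["rerupture_surgery"])
    c_major = params.complication_costs.major_cost
    c_minor = params.complication_costs.minor_cost
    single = util.decrement_duration == "single_cycle"

    def sched(k: int) -> float:
        idx = min(k, len(util.recovery_utilities)) - 1
        return util.recovery_utilities[idx]

    def tail_utility(start_cycle: int, mult: float) -> float:
        # utility accrued from start_cycle..n for a pathway entered with
        # a fresh clock at start_cycle - 1 (k=2 at start_cycle)
        total = 0.0
        for cycle in range(start_cycle, n + 1):
            k = cycle - start_cycle + 2
            m = mult if (not single or k == 2) else 1.0
            total += sched(k) * m
        return total

    def treat(cycle: int, rates, episode_cost: float) -> tuple[float, float]:
        """Expected (cost, utility-sum) per unit mass treated at `cycle`."""
        cost = episode_cost
        utility = sched(1)  # recovery cycle
        p_full = 1.0 - (rates.p_rerupture + rates.p_major + rates.p_minor)
        # event costs at end of the treatment cycle
        cost += rates.p_major * c_major + rates.p_minor * c_minor
        utility += p_full * tail_utility(cycle + 1, 1.0)
        utility += rates.p_minor * tail_utility(cycle + 1, util.minor_multiplier)
        utility += rates.p_major * tail_utility(cycle + 1, util.major_multiplier)
        if cycle < n and rates.p_rerupture > 0:
            sub_cost, sub_util = treat(
                cycle + 1, params.rates_operative, rerup_cost
            )
            cost += rates.p_rerupture * sub_cost
            utility += rates.p_rerupture * sub_util
        return cost, utility

    initial_rates = (
        params.rates_operative if strategy == "operative" else params.rates_nonoperative
    )
    cost, utility = treat(1, initial_rates, initial_cost)
    return cost, utility * dt * u_scale


def assert_conserved(params: ParameterSet) -> None:
    """Occupancy rows of both strategy traces sum to one."""
    for strategy in ("operative", "non_operative"):
        trace = run_cohort(strategy, params).trace
        sums = trace.occupancy.sum(axis=1)
        assert np.all(np.abs(sums - 1.0) < 1e-9)
        assert np.all(trace.occupancy >= -1e-15)
        assert np.all(trace.occupancy <= 1.0 + 1e-12)


def make_random_params(seed: int, n_cycles: int = 8) -> ParameterSet:
    return random_scenario(np.random.default_rng(seed), n_cycles=n_cycles).params
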