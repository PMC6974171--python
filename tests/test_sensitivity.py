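import math

import numpy as np
import pandas as pd
import pytest

from achilles_cea import (
    NoThresholdError,
    PsaDistributionSpec,
    SweepSpec,
    ceac,
    default_psa_specs,
    find_threshold,
    one_way_sweep,
    run_both,
    run_cohort,
    run_psa,
    sample_parameter_set,
    set_param,
    tornado,
)
from achilles_cea.cli import default_tornado_specs
from achilles_cea.sensitivity import ConfigurationError


class TestOneWaySweep:
    def test_hospitalization_sweep_flips_preference_once(self, calibrated_params):
        spec = SweepSpec(
            parameter_path="episode_costs.operative.hospitalization",
            low=0.0, high=6000.0, n_points=25,
        )
        table = one_way_sweep(spec, calibrated_params, wtp=50_000.0)
        flips = (table["preferred"] != table["preferred"].shift()).iloc[1:].sum()
        assert flips == 1
        # delta cost rises linearly with operative hospitalization
        assert table["delta_cost"].is_monotonic_increasing

    def test_degenerate_range_repeats_single_row(self, calibrated_params):
        spec = SweepSpec(
            parameter_path="wage.hourly_wage", low=24.0, high=24.0, n_points=3
        )
        table = one_way_sweep(spec, calibrated_params)
        assert table.nunique().max() == 1 or len(table.drop_duplicates()) == 1

    def test_utility_penalty_sweep_monotone(self, calibrated_params):
        spec = SweepSpec(
            parameter_path="nonoperative_utility_penalty",
            low=0.0, high=0.05, n_points=6,
        )
        table = one_way_sweep(spec, calibrated_params)
        # larger non-operative decrement -> operative gains QALYs relatively
        assert table["delta_qalys"].is_monotonic_increasing

    def test_invalid_range_fails_before_evaluation(self, calibrated_params):
        spec = SweepSpec(
            parameter_path="rates_operative.p_minor", low=0.5, high=1.5, n_points=3
        )
        with pytest.raises(Exception):
            one_way_sweep(spec, calibrated_params)


class TestFindThreshold:
    def test_hospitalization_cost_parity_threshold(self, calibrated_params):
        result = find_threshold(
            "episode_costs.operative.hospitalization",
            (0.0, 6000.0),
            calibrated_params,
            criterion="cost_parity",
        )
        # ICER arithmetic: 3145 - 523.34 incremental cost
        assert result.threshold_value == pytest.approx(2621.66, abs=0.05)
        assert result.operative_preferred_below()

    def test_hourly_wage_threshold_rounds_to_29(self, calibrated_params):
        result = find_threshold(
            "wage.hourly_wage", (1.0, 100.0), calibrated_params,
            criterion="cost_parity",
        )
        assert round(result.threshold_value) == 29
        assert result.direction == "operative_above"

    def test_utility_decrement_threshold_rounds_to_2_percent(self, calibrated_params):
        result = find_threshold(
            "nonoperative_utility_penalty", (0.0, 0.2), calibrated_params,
            wtp=50_000.0, criterion="nmb_flip",
        )
        assert round(100 * result.threshold_value) == 2

    def test_threshold_verified_by_flanking_evaluations(self, calibrated_params):
        result = find_threshold(
            "episode_costs.operative.hospitalization", (0.0, 6000.0),
            calibrated_params, criterion="cost_parity",
        )

        def cost_gap(v):
            p = set_param(
                calibrated_params, "episode_costs.operative.hospitalization", v
            )
            out = run_both(p)
            return out["operative"].total_cost - out["non_operative"].total_cost

        assert cost_gap(result.threshold_value - 0.05) < 0
        assert cost_gap(result.threshold_value + 0.05) > 0

    def test_no_flip_in_range_is_an_error(self, calibrated_params):
        with pytest.raises(NoThresholdError):
            find_threshold(
                "episode_costs.operative.hospitalization", (3000.0, 6000.0),
                calibrated_params, criterion="cost_parity",
            )


class TestTornado:
    def test_relative_utilities_lead_the_ranking(self, calibrated_params):
        """The relative quality of life between arms is the single most
        influential parameter, with operative hospitalization cost also
        near the top — the model's dominant sensitivities."""
        specs = default_tornado_specs(calibrated_params)
        table = tornado(specs, calibrated_params, wtp=50_000.0)
        top3 = set(table["parameter_path"].head(3))
        assert "nonoperative_utility_penalty" in top3
        assert "episode_costs.operative.hospitalization" in top3
        # ranking is by the width of the NMB interval, descending
        assert table["range"].is_monotonic_decreasing

    def test_event_rate_ci_sweeps_do_not_flip_the_decision(self, calibrated_params):
        specs = [
            s for s in default_tornado_specs(calibrated_params)
            if s.parameter_path.startswith("rates_operative.")
        ]
        table = tornado(specs, calibrated_params, wtp=50_000.0)
        # positive gap = non-operative preferred, at both range endpoints
        assert (table["nmb_gap_at_low"] > 0).all()
        assert (table["nmb_gap_at_high"] > 0).all()

    def test_single_spec_single_row(self, calibrated_params):
        table = tornado(
            [SweepSpec(parameter_path="wage.hourly_wage", low=20.0, high=30.0)],
            calibrated_params,
        )
        assert len(table) == 1

    def test_empty_specs_rejected(self, calibrated_params):
        with pytest.raises(ConfigurationError):
            tornado([], calibrated_params)


class TestDistributionSampling:
    def test_lognormal_matches_ci_parameterization(self):
        spec = PsaDistributionSpec(
            parameter_path="relative_risks.rerupture", family="lognormal",
            point=0.40, ci_low=0.12, ci_high=1.32,
        )
        draws = spec.sample(np.random.default_rng(0), 100_000)
        logs = np.log(draws)
        sigma = (math.log(1.32) - math.log(0.12)) / 3.92
        assert logs.mean() == pytest.approx(math.log(0.40), abs=4 * sigma / math.sqrt(1e5))
        assert logs.std() == pytest.approx(sigma, rel=0.02)

    def test_gamma_moment_matching(self):
        se = (3244.0 - 3045.0) / 3.92
        spec = PsaDistributionSpec(
            parameter_path="episode_costs.operative.hospitalization",
            family="gamma", mean=3145.0, se=se,
        )
        draws = spec.sample(np.random.default_rng(1), 100_000)
        assert draws.mean() == pytest.approx(3145.0, abs=1.0)
        assert draws.std() == pytest.approx(se, rel=0.02)
        assert (draws > 0).all()

    def test_beta_moment_matching_and_support(self):
        spec = PsaDistributionSpec(
            parameter_path="rates_nonoperative.p_rerupture",
            family="beta", mean=0.096, se=0.2 * 0.096,
        )
        draws = spec.sample(np.random.default_rng(2), 100_000)
        assert draws.mean() == pytest.approx(0.096, abs=0.001)
        assert ((draws > 0) & (draws < 1)).all()

    def test_truncated_normal_respects_bounds(self):
        spec = PsaDistributionSpec(
            parameter_path="utilities.recovery_utilities.2",
            family="normal_truncated", mean=0.9, se=0.05, lower=0.0, upper=1.0,
        )
        draws = spec.sample(np.random.default_rng(3), 50_000)
        assert draws.max() <= 1.0 and draws.min() >= 0.0
        assert draws.mean() == pytest.approx(0.894, abs=0.005)  # truncation shifts down

    def test_zero_se_degenerates_to_mean(self):
        spec = PsaDistributionSpec(
            parameter_path="wage.hourly_wage", family="gamma", mean=24.48, se=0.0
        )
        assert (spec.sample(np.random.default_rng(4), 10) == 24.48).all()

    def test_infeasible_beta_moments_rejected(self):
        spec = PsaDistributionSpec(
            parameter_path="rates_nonoperative.p_major", family="beta",
            mean=0.5, se=0.6,
        )
        with pytest.raises(ConfigurationError):
            spec.sample(np.random.default_rng(5), 10)


class TestSampleParameterSet:
    def test_zero_variance_specs_return_base_case(self, calibrated_params):
        specs = [
            s.model_copy(update={"se": 0.0}) if s.se is not None else s
            for s in default_psa_specs(calibrated_params)
        ]
        specs = [
            s.model_copy(update={"ci_low": s.point, "ci_high": s.point})
            if s.family == "lognormal" else s
            for s in specs
        ]
        sampled = sample_parameter_set(
            np.random.default_rng(0), specs, calibrated_params
        )
        # PSA re-derives operative rates as RR x non-operative rate, so
        # the degenerate draw reproduces the base case with the derived
        # (rather than the tabulated) operative rates; the two differ by
        # under 0.2 percentage points per event.
        from achilles_cea import derive_operative_rates

        reference = set_param(
            calibrated_params,
            "rates_operative",
            derive_operative_rates(
                calibrated_params.relative_risks,
                calibrated_params.rates_nonoperative,
            ),
        )
        base = run_both(reference)
        got = run_both(sampled)
        for strategy in got:
            assert got[strategy].total_cost == pytest.approx(
                base[strategy].total_cost, abs=1e-6
            )
            assert got[strategy].total_qalys == pytest.approx(
                base[strategy].total_qalys, abs=1e-9
            )

    def test_sampled_sets_are_valid_and_coherent(self, calibrated_params):
        """Operative rates must equal sampled RR x sampled non-operative
        rate (clipped), propagating uncertainty coherently."""
        rng = np.random.default_rng(11)
        specs = default_psa_specs(calibrated_params)
        for _ in range(20):
            s = sample_parameter_set(rng, specs, calibrated_params)
            expected = s.relative_risks["rerupture"].point * s.rates_nonoperative.p_rerupture
            total = (
                s.rates_operative.p_rerupture
                + s.rates_operative.p_major
                + s.rates_operative.p_minor
            )
            assert total <= 1.0
            if total < 0.999 - 1e-9:
                assert s.rates_operative.p_rerupture == pytest.approx(
                    min(1.0, expected), rel=1e-9
                )
            sched = s.utilities.recovery_utilities
            assert all(b >= a for a, b in zip(sched, sched[1:]))


class TestRunPsa:
    def test_same_seed_bitwise_identical(self, calibrated_params):
        a = run_psa(calibrated_params, n=40, seed=123)
        b = run_psa(calibrated_params, n=40, seed=123)
        pd.testing.assert_frame_equal(a.draws, b.draws)
        pd.testing.assert_frame_equal(a.acceptability, b.acceptability)

    def test_zero_variance_reduces_to_deterministic_dominance(self, calibrated_params):
        specs = [
            s.model_copy(update={"se": 0.0}) if s.se is not None
            else s.model_copy(update={"ci_low": s.point, "ci_high": s.point})
            if s.family == "lognormal" else s
            for s in default_psa_specs(calibrated_params)
        ]
        result = run_psa(calibrated_params, dist_specs=specs, n=20, seed=9)
        assert result.acceptability_at(50_000.0, "non_operative") == 1.0

    def test_acceptability_fractions_complementary(self, calibrated_params):
        result = run_psa(calibrated_params, n=200, seed=42)
        acc = result.acceptability
        assert ((acc["fraction_nonoperative"] + acc["fraction_operative"]) == 1.0).all()
        assert acc["fraction_nonoperative"].between(0, 1).all()

    def test_ceac_grid_and_bounds(self, calibrated_params):
        result = run_psa(calibrated_params, n=200, seed=42)
        curve = ceac(result, np.linspace(0, 100_000, 11))
        assert len(curve) == 11
        assert curve["fraction_operative"].between(0, 1).all()

    def test_spec_echo_records_sampling_plan(self, calibrated_params):
        result = run_psa(calibrated_params, n=10, seed=1)
        paths = [s.parameter_path for s in result.spec_echo]
        assert "rates_nonoperative.p_rerupture" in paths
        assert "utilities_nonoperative.recovery_utilities.2" in paths
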