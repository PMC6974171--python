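"""Deterministic and probabilistic sensitivity analysis.

One-way sweeps move a single parameter over a range while everything
else stays at base case; the threshold finder bisects for the value at
which the preferred strategy flips, under either of two criteria:

* ``nmb_flip`` — the sign of the net-monetary-benefit difference at a
  willingness-to-pay threshold changes (the textbook decision rule);
* ``cost_parity`` — the two strategies' total expected costs cross.
  With the non-operative arm both cheaper and more effective at base
  case, the published flip points behave as cost parity, so this is the
  default criterion.

The probabilistic sensitivity analysis re-samples every uncertain input
simultaneously — beta distributions for event probabilities, lognormal
for relative risks (parameterized from their 95% CIs), gamma for costs,
and truncated normal for utilities — runs the cohort model on each
draw, and summarizes the fraction of draws in which each strategy has
the highest net monetary benefit (the cost-effectiveness acceptability
curve).  Draws are consumed in a fixed, documented parameter order from
a single seeded generator, so runs reproduce bit-for-bit.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict
from scipy import stats

from .engine import run_cohort
from .parameters import (
    InvalidParameterError,
    ParameterSet,
    get_param,
    set_param,
)

_TIE_EPS = 1e-9
# Width of a 95% normal interval in standard errors: CI-derived SEs use
# se = (hi - lo) / 3.92 and lognormal sigma = (ln hi - ln lo) / 3.92.
_CI_WIDTH = 3.92


class ConfigurationError(ValueError):
    """A sensitivity-analysis specification is unusable."""


# ---------------------------------------------------------------------------
# One-way sweeps, threshold search, tornado ranking
# ---------------------------------------------------------------------------

class SweepSpec(BaseModel):
    """A one-way sweep of one scalar parameter."""

    model_config = ConfigDict(frozen=True)

    parameter_path: str
    low: float
    high: float
    n_points: int = 11

    def values(self) -> np.ndarray:
        if self.low > self.high:
            raise ConfigurationError(
                f"sweep low {self.low} exceeds high {self.high}"
            )
        return np.linspace(self.low, self.high, self.n_points)


def _evaluate(params: ParameterSet, path: str, value: float):
    probe = set_param(params, path, float(value))
    return run_cohort("operative", probe), run_cohort("non_operative", probe)


def one_way_sweep(
    spec: SweepSpec, params: ParameterSet, wtp: float = 50_000.0
) -> pd.DataFrame:
    """Evaluate the model along one parameter sweep.

    Returns one row per grid point with the incremental cost and QALYs
    of operative over non-operative management and the NMB-preferred
    strategy at ``wtp``.  The range is validated against the parameter's
    invariants before any model evaluation.
    """
    values = spec.values()
    for v in (values[0], values[-1]):  # fail fast on invariant violations
        set_param(params, spec.parameter_path, float(v))
    rows = []
    for v in values:
        op, non = _evaluate(params, spec.parameter_path, v)
        d_cost = op.total_cost - non.total_cost
        d_q = op.total_qalys - non.total_qalys
        rows.append(
            {
                "value": float(v),
                "total_cost_operative": op.total_cost,
                "total_cost_nonoperative": non.total_cost,
                "delta_cost": d_cost,
                "delta_qalys": d_q,
                "preferred": "operative"
                if wtp * d_q - d_cost > _TIE_EPS
                else "non_operative",
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ThresholdResult:
    """A parameter value at which the preferred strategy flips."""

    parameter_path: str
    threshold_value: float
    wtp: float
    criterion: str
    direction: str  # which side of the threshold prefers operative care

    def operative_preferred_below(self) -> bool:
        return self.direction == "operative_below"


def _operative_preferred(
    params: ParameterSet, path: str, value: float, wtp: float, criterion: str
) -> bool:
    op, non = _evaluate(params, path, value)
    if criterion == "cost_parity":
        return op.total_cost < non.total_cost - _TIE_EPS
    if criterion == "nmb_flip":
        diff = wtp * (op.total_qalys - non.total_qalys) - (
            op.total_cost - non.total_cost
        )
        return diff > _TIE_EPS
    raise ConfigurationError(f"unknown threshold criterion {criterion!r}")


def default_tolerance(parameter_path: str) -> float:
    """Bisection tolerance: 1e-4 on probabilities/utilities, $0.01 on money."""
    head = parameter_path.split(".")[0]
    if head in ("rates_nonoperative", "rates_operative", "utilities",
                "relative_risks", "nonoperative_utility_penalty"):
        return 1e-4
    return 0.01


def find_threshold(
    parameter_path: str,
    bounds: tuple[float, float],
    params: ParameterSet,
    wtp: float = 50_000.0,
    criterion: Literal["nmb_flip", "cost_parity"] = "cost_parity",
    tolerance: Optional[float] = None,
) -> ThresholdResult:
    """Bisect for the parameter value where the preferred strategy flips.

    Raises :class:`NoThresholdError` when both bounds yield the same
    preference under the chosen criterion.
    """
    lo, hi = float(bounds[0]), float(bounds[1])
    if lo >= hi:
        raise ConfigurationError("bounds must satisfy low < high")
    tol = default_tolerance(parameter_path) if tolerance is None else tolerance
    pref_lo = _operative_preferred(params, parameter_path, lo, wtp, criterion)
    pref_hi = _operative_preferred(params, parameter_path, hi, wtp, criterion)
    if pref_lo == pref_hi:
        raise NoThresholdError(
            f"no threshold in range [{lo}, {hi}] for {parameter_path!r}: "
            f"operative preferred at both bounds is {pref_lo}"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _operative_preferred(params, parameter_path, mid, wtp, criterion) == pref_lo:
            lo = mid
        else:
            hi = mid
    return ThresholdResult(
        parameter_path=parameter_path,
        threshold_value=0.5 * (lo + hi),
        wtp=wtp,
        criterion=criterion,
        direction="operative_below" if pref_lo else "operative_above",
    )


class NoThresholdError(RuntimeError):
    """Both sweep bounds prefer the same strategy."""


def tornado(
    specs: Sequence[SweepSpec], params: ParameterSet, wtp: float = 50_000.0
) -> pd.DataFrame:
    """Rank parameters by their leverage on the incremental NMB.

    For each spec, the net-monetary-benefit difference (non-operative
    minus operative, so positive favours non-operative care) is
    evaluated at the two range endpoints; parameters are sorted by the
    absolute width of that interval, the classic tornado ordering.
    """
    if not specs:
        raise ConfigurationError("tornado requires at least one sweep spec")

    def nmb_gap(p: ParameterSet) -> float:
        op = run_cohort("operative", p)
        non = run_cohort("non_operative", p)
        return wtp * (non.total_qalys - op.total_qalys) - (
            non.total_cost - op.total_cost
        )

    base_gap = nmb_gap(params)
    rows = []
    for spec in specs:
        gap_lo = nmb_gap(set_param(params, spec.parameter_path, spec.low))
        gap_hi = nmb_gap(set_param(params, spec.parameter_path, spec.high))
        rows.append(
            {
                "parameter_path": spec.parameter_path,
                "low": spec.low,
                "high": spec.high,
                "nmb_gap_at_low": gap_lo,
                "nmb_gap_at_high": gap_hi,
                "nmb_gap_base": base_gap,
                "range": abs(gap_hi - gap_lo),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("range", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

class PsaDistributionSpec(BaseModel):
    """Sampling distribution for one uncertain parameter.

    Families follow the parameter's role: ``beta`` for probabilities
    (method-of-moments from mean and SE), ``gamma`` for costs (same),
    ``lognormal`` for relative risks (log-mean at the point estimate,
    log-SD from the 95% CI), ``normal_truncated`` for utilities, and
    ``fixed`` for parameters held at base case.  A zero SE degenerates
    to the mean.
    """

    model_config = ConfigDict(frozen=True)

    parameter_path: str
    family: Literal["beta", "gamma", "lognormal", "normal_truncated", "fixed"]
    mean: Optional[float] = None
    se: Optional[float] = None
    point: Optional[float] = None
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    lower: float = 0.0
    upper: float = 1.0

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "fixed":
            return np.full(n, self.mean)
        if self.family == "lognormal":
            if self.point is None or self.ci_low is None or self.ci_high is None:
                raise ConfigurationError(
                    f"lognormal spec for {self.parameter_path!r} needs point and CI"
                )
            sigma = (math.log(self.ci_high) - math.log(self.ci_low)) / _CI_WIDTH
            if sigma == 0:
                return np.full(n, self.point)
            return rng.lognormal(mean=math.log(self.point), sigma=sigma, size=n)
        if self.mean is None or self.se is None:
            raise ConfigurationError(
                f"{self.family} spec for {self.parameter_path!r} needs mean and SE"
            )
        m, s = self.mean, self.se
        if s == 0 or m == 0 and self.family == "gamma":
            return np.full(n, m)
        v = s * s
        if self.family == "beta":
            if not 0 < m < 1 or v >= m * (1 - m):
                raise ConfigurationError(
                    f"beta moments infeasible for {self.parameter_path!r} "
                    f"(mean={m}, se={s})"
                )
            common = m * (1 - m) / v - 1
            return rng.beta(m * common, (1 - m) * common, size=n)
        if self.family == "gamma":
            return rng.gamma(shape=m * m / v, scale=v / m, size=n)
        if self.family == "normal_truncated":
            a, b = (self.lower - m) / s, (self.upper - m) / s
            return stats.truncnorm.rvs(a, b, loc=m, scale=s, size=n, random_state=rng)
        raise ConfigurationError(f"unknown family {self.family!r}")


# Default spread assumptions for parameters whose uncertainty the source
# tables do not quantify: SE = 10% of the mean for costs, 20% of the
# mean for probabilities, SD = 0.05 for utilities.  CI-derived spreads
# are used wherever a CI is printed (relative risks, operative
# hospitalization cost).
DEFAULT_COST_SE_FRACTION = 0.10
DEFAULT_RATE_SE_FRACTION = 0.20
DEFAULT_UTILITY_SD = 0.05


def default_psa_specs(params: ParameterSet) -> list[PsaDistributionSpec]:
    """The documented default sampling plan, in draw order."""
    specs: list[PsaDistributionSpec] = []
    rates = params.rates_nonoperative
    for name in ("p_rerupture", "p_major", "p_minor"):
        m = getattr(rates, name)
        specs.append(
            PsaDistributionSpec(
                parameter_path=f"rates_nonoperative.{name}",
                family="beta",
                mean=m,
                se=DEFAULT_RATE_SE_FRACTION * m,
            )
        )
    for event in ("rerupture", "major_complication", "minor_complication"):
        rr = params.relative_risks[event]
        specs.append(
            PsaDistributionSpec(
                parameter_path=f"relative_risks.{event}",
                family="lognormal",
                point=rr.point,
                ci_low=rr.ci_low,
                ci_high=rr.ci_high,
            )
        )
    op_hosp = params.episode_costs["operative"]
    hosp_se = (
        (op_hosp.hospitalization_ci[1] - op_hosp.hospitalization_ci[0]) / _CI_WIDTH
        if op_hosp.hospitalization_ci is not None
        else DEFAULT_COST_SE_FRACTION * op_hosp.hospitalization
    )
    cost_paths: list[tuple[str, float, float]] = [
        ("episode_costs.operative.hospitalization", op_hosp.hospitalization, hosp_se),
        (
            "episode_costs.rerupture_surgery.hospitalization",
            params.episode_costs["rerupture_surgery"].hospitalization,
            DEFAULT_COST_SE_FRACTION
            * params.episode_costs["rerupture_surgery"].hospitalization,
        ),
        (
            "episode_costs.operative.surgeon",
            params.episode_costs["operative"].surgeon,
            DEFAULT_COST_SE_FRACTION * params.episode_costs["operative"].surgeon,
        ),
        (
            "episode_costs.non_operative.surgeon",
            params.episode_costs["non_operative"].surgeon,
            DEFAULT_COST_SE_FRACTION * params.episode_costs["non_operative"].surgeon,
        ),
        (
            "episode_costs.rerupture_surgery.surgeon",
            params.episode_costs["rerupture_surgery"].surgeon,
            DEFAULT_COST_SE_FRACTION
            * params.episode_costs["rerupture_surgery"].surgeon,
        ),
        (
            "episode_costs.operative.physical_therapy",
            params.episode_costs["operative"].physical_therapy,
            DEFAULT_COST_SE_FRACTION
            * params.episode_costs["operative"].physical_therapy,
        ),
        (
            "wage.hourly_wage",
            params.wage.hourly_wage,
            DEFAULT_COST_SE_FRACTION * params.wage.hourly_wage,
        ),
    ]
    for path, m, s in cost_paths:
        specs.append(
            PsaDistributionSpec(parameter_path=path, family="gamma", mean=m, se=s)
        )
    # Per-event complication costs: gamma where positive; a calibrated
    # negative component has no gamma representation and is held fixed.
    for comp, value in (
        ("major_cost", params.complication_costs.major_cost),
        ("minor_cost", params.complication_costs.minor_cost),
    ):
        if value > 0:
            specs.append(
                PsaDistributionSpec(
                    parameter_path=f"complication_costs.{comp}",
                    family="gamma",
                    mean=value,
                    se=DEFAULT_COST_SE_FRACTION * value,
                )
            )
        else:
            specs.append(
                PsaDistributionSpec(
                    parameter_path=f"complication_costs.{comp}",
                    family="fixed",
                    mean=value,
                )
            )
    # Per-arm utility schedules: the deterministic analyses treat the
    # non-operative arm's quality of life as a parameter in its own
    # right, so the PSA samples the two arms' schedules separately
    # (complication decrements stay shared between arms).
    for prefix in ("utilities", "utilities_nonoperative"):
        for i, u in enumerate(params.utilities.recovery_utilities):
            specs.append(
                PsaDistributionSpec(
                    parameter_path=f"{prefix}.recovery_utilities.{i}",
                    family="normal_truncated",
                    mean=u,
                    se=DEFAULT_UTILITY_SD,
                    lower=0.0,
                    upper=1.0,
                )
            )
    for mult in ("minor_multiplier", "major_multiplier"):
        specs.append(
            PsaDistributionSpec(
                parameter_path=f"utilities.{mult}",
                family="normal_truncated",
                mean=getattr(params.utilities, mult),
                se=DEFAULT_UTILITY_SD,
                lower=1e-6,
                upper=1.0,
            )
        )
    return specs


def _assemble(base_data: dict, values: dict[str, float]) -> ParameterSet:
    """Build a sampled ParameterSet from drawn values, keeping invariants.

    Operative event rates are re-derived as sampled relative risk times
    sampled non-operative rate (clipped to [0, 1]; in the rare draw
    whose event probabilities leave no full-benefit mass, the triple is
    rescaled proportionally to sum 0.999).  Sampled utility schedules
    are made non-decreasing by a running maximum, and anything sampled
    under ``wage.`` propagates into the missed-work cost components.
    """
    data = copy.deepcopy(base_data)
    data["utilities"]["recovery_utilities"] = list(
        data["utilities"]["recovery_utilities"]
    )
    if any(path.startswith("utilities_nonoperative.") for path in values):
        if data.get("utilities_nonoperative") is None:
            data["utilities_nonoperative"] = copy.deepcopy(data["utilities"])
        data["utilities_nonoperative"]["recovery_utilities"] = list(
            data["utilities_nonoperative"]["recovery_utilities"]
        )
    rr_points: dict[str, float] = {}
    util_sampled = False
    for path, value in values.items():
        parts = path.split(".")
        if parts[0] == "relative_risks":
            event = parts[1]
            rr_points[event] = value
            entry = data["relative_risks"][event]
            entry["point"] = value
            entry["ci_low"] = min(entry["ci_low"], value)
            entry["ci_high"] = max(entry["ci_high"], value)
            continue
        if parts[0] in ("utilities", "utilities_nonoperative"):
            util_sampled = True
        node = data
        for part in parts[:-1]:
            node = node[part]
        leaf = parts[-1]
        if isinstance(node, list):
            node[int(leaf)] = value
        elif isinstance(node, dict) and leaf in node:
            node[leaf] = value
        else:
            raise KeyError(path)

    # non-operative rates: keep a sliver of full-benefit mass
    nonop = data["rates_nonoperative"]
    total = nonop["p_rerupture"] + nonop["p_major"] + nonop["p_minor"]
    if total > 0.999:
        scale = 0.999 / total
        for key in ("p_rerupture", "p_major", "p_minor"):
            nonop[key] *= scale

    # operative rates from sampled relative risks x non-operative rates
    if rr_points:
        pairs = {
            "p_rerupture": "rerupture",
            "p_major": "major_complication",
            "p_minor": "minor_complication",
        }
        op = {
            rate_key: min(
                1.0, data["relative_risks"][ev]["point"] * nonop[rate_key]
            )
            for rate_key, ev in pairs.items()
        }
        total = sum(op.values())
        if total > 0.999:
            op = {k: v * 0.999 / total for k, v in op.items()}
        data["rates_operative"] = op

    if util_sampled:
        for key in ("utilities", "utilities_nonoperative"):
            block = data.get(key)
            if block is None:
                continue
            sched = np.maximum.accumulate(block["recovery_utilities"])
            block["recovery_utilities"] = [float(u) for u in sched]
            block["full_benefit_utility"] = float(sched[-1])
        # complication decrements are shared between arms
        if data.get("utilities_nonoperative") is not None:
            for mult in ("minor_multiplier", "major_multiplier"):
                data["utilities_nonoperative"][mult] = data["utilities"][mult]

    if any(path.startswith("wage.") for path in values):
        wage = data["wage"]
        for kind, weeks in wage["weeks_missed"].items():
            data["episode_costs"][kind]["missed_work"] = (
                weeks * wage["hours_per_week"] * wage["hourly_wage"]
            )
    return ParameterSet.model_validate(data)


def sample_parameter_set(
    rng: np.random.Generator,
    dist_specs: Sequence[PsaDistributionSpec],
    base: ParameterSet,
) -> ParameterSet:
    """Draw one valid parameter set (specs consumed in list order)."""
    values = {
        spec.parameter_path: float(spec.sample(rng, 1)[0]) for spec in dist_specs
    }
    return _assemble(base.model_dump(), values)


@dataclass(frozen=True)
class PsaResult:
    """Monte Carlo draws and their decision summary.

    ``draws`` holds one row per iteration with the incremental cost and
    QALYs of operative over non-operative care plus the NMB-preferred
    strategy at each willingness-to-pay in the grid; ``acceptability``
    gives the fraction of draws won by each strategy per threshold.
    """

    draws: pd.DataFrame
    seed: int
    wtp_grid: tuple[float, ...]
    acceptability: pd.DataFrame
    spec_echo: tuple[PsaDistributionSpec, ...]

    def acceptability_at(self, wtp: float, strategy: str = "non_operative") -> float:
        row = self.acceptability[np.isclose(self.acceptability["wtp"], wtp)]
        if row.empty:
            raise KeyError(f"wtp {wtp} not in acceptability grid")
        column = f"fraction_{strategy.replace('_', '')}"
        return float(row[column].iloc[0])


def _acceptability_frame(
    d_cost: np.ndarray, d_q: np.ndarray, wtp_grid: Iterable[float]
) -> pd.DataFrame:
    rows = []
    for wtp in wtp_grid:
        op_wins = (wtp * d_q - d_cost) > _TIE_EPS
        rows.append(
            {
                "wtp": float(wtp),
                "fraction_nonoperative": float(1.0 - op_wins.mean()),
                "fraction_operative": float(op_wins.mean()),
            }
        )
    return pd.DataFrame(rows)


def run_psa(
    params: ParameterSet,
    dist_specs: Optional[Sequence[PsaDistributionSpec]] = None,
    n: Optional[int] = None,
    seed: Optional[int] = None,
    wtp_grid: Optional[Sequence[float]] = None,
) -> PsaResult:
    """Monte Carlo probabilistic sensitivity analysis.

    Draws ``n`` parameter sets (defaults to the run settings' iteration
    count) from ``dist_specs`` (defaults to the documented sampling
    plan), runs both strategies through the cohort engine for each, and
    tallies the NMB-preferred strategy at every willingness-to-pay in
    the grid.  Fully reproducible from the seed: each spec's draws are
    generated as one vector, in spec order, from a single generator.
    """
    if dist_specs is None:
        dist_specs = default_psa_specs(params)
    if n is None:
        n = params.settings.psa_iterations
    if seed is None:
        seed = params.settings.seed
    if wtp_grid is None:
        wtp_grid = params.settings.wtp_grid
    if n < 1:
        raise ConfigurationError("PSA needs at least one iteration")

    rng = np.random.default_rng(seed)
    columns = {
        spec.parameter_path: spec.sample(rng, n) for spec in dist_specs
    }
    base_data = params.model_dump()
    d_cost = np.empty(n)
    d_q = np.empty(n)
    for i in range(n):
        draw = {path: float(col[i]) for path, col in columns.items()}
        sampled = _assemble(base_data, draw)
        op = run_cohort("operative", sampled)
        non = run_cohort("non_operative", sampled)
        d_cost[i] = op.total_cost - non.total_cost
        d_q[i] = op.total_qalys - non.total_qalys

    draws = pd.DataFrame(
        {"draw_index": np.arange(n), "delta_cost": d_cost, "delta_qalys": d_q}
    )
    for wtp in wtp_grid:
        op_wins = (wtp * d_q - d_cost) > _TIE_EPS
        draws[f"preferred_at_{int(wtp)}"] = np.where(
            op_wins, "operative", "non_operative"
        )
    return PsaResult(
        draws=draws,
        seed=seed,
        wtp_grid=tuple(float(w) for w in wtp_grid),
        acceptability=_acceptability_frame(d_cost, d_q, wtp_grid),
        spec_echo=tuple(dist_specs),
    )


def ceac(
    result: PsaResult, wtp_grid: Optional[Sequence[float]] = None
) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve from stored PSA draws."""
    if wtp_grid is None:
        wtp_grid = np.linspace(0, 200_000, 81)
    return _acceptability_frame(
        result.draws["delta_cost"].to_numpy(),
        result.draws["delta_qalys"].to_numpy(),
        wtp_grid,
    )
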