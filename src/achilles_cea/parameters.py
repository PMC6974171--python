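"""Model inputs for the Achilles tendon rupture cost-utility analysis.

Every number the decision model consumes lives here: per-episode event
probabilities (re-rupture, major and minor complications), the relative
risks of those events under operative versus non-operative management,
the cost build-up of each treatment episode (hospitalization, surgeon,
physical therapy, missed work), per-event complication costs, the wage
model behind indirect costs, the time-dependent utility schedule, and
the run settings of the Markov cohort engine (cycle length, horizon,
willingness-to-pay grid, PSA iterations).

All monetary amounts are 2014 US dollars, carried as floats at full
precision; rounding to dollars or cents happens only at reporting time.
"""

from __future__ import annotations

from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

EpisodeKind = Literal["operative", "non_operative", "rerupture_surgery"]
EventName = Literal["rerupture", "major_complication", "minor_complication"]

EPISODE_KINDS: tuple[EpisodeKind, ...] = (
    "operative",
    "non_operative",
    "rerupture_surgery",
)


class InvalidParameterError(ValueError):
    """A parameter combination violates a model invariant."""


class _Frozen(BaseModel):
    model_config = ConfigDict(frozen=True, extra="forbid")


class RelativeRisk(_Frozen):
    """Relative risk of an event under operative vs. non-operative care.

    ``point`` is the meta-analytic point estimate; ``ci_low``/``ci_high``
    bound its 95% confidence interval and parameterize the lognormal
    sampling distribution used in probabilistic sensitivity analysis.
    """

    event: EventName
    point: float = Field(gt=0)
    ci_low: float = Field(gt=0)
    ci_high: float = Field(gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "RelativeRisk":
        if not (self.ci_low <= self.point <= self.ci_high):
            raise ValueError(
                f"relative risk CI must bracket the point estimate: "
                f"{self.ci_low} <= {self.point} <= {self.ci_high} fails"
            )
        return self


class EventRates(_Frozen):
    """Per-treatment-episode probabilities of each adverse outcome.

    The remainder ``1 - (p_rerupture + p_major + p_minor)`` is the
    probability of progressing to the full-benefit state.
    """

    p_rerupture: float = Field(ge=0, le=1)
    p_major: float = Field(ge=0, le=1)
    p_minor: float = Field(ge=0, le=1)

    @model_validator(mode="after")
    def _sub_stochastic(self) -> "EventRates":
        total = self.p_rerupture + self.p_major + self.p_minor
        if total > 1 + 1e-12:
            raise ValueError(
                f"event probabilities sum to {total:.4f} > 1 "
                f"(rerupture={self.p_rerupture}, major={self.p_major}, "
                f"minor={self.p_minor})"
            )
        return self

    @property
    def p_full_benefit(self) -> float:
        return max(0.0, 1.0 - (self.p_rerupture + self.p_major + self.p_minor))


class EpisodeCosts(_Frozen):
    """Direct and indirect cost components of one treatment episode."""

    kind: EpisodeKind
    hospitalization: float = Field(ge=0)
    hospitalization_ci: Optional[tuple[float, float]] = None
    surgeon: float = Field(ge=0)
    physical_therapy: float = Field(ge=0)
    missed_work: float = Field(ge=0)

    @model_validator(mode="after")
    def _nonoperative_no_hospital(self) -> "EpisodeCosts":
        if self.kind == "non_operative" and self.hospitalization != 0:
            raise ValueError("non-operative episodes carry no hospitalization cost")
        if self.hospitalization_ci is not None:
            lo, hi = self.hospitalization_ci
            # the CI enters the model only through its width (PSA spread),
            # so it need not bracket a swept point estimate
            if not (0 <= lo <= hi):
                raise ValueError("hospitalization CI must be ordered and >= 0")
        return self


class ComplicationEventCosts(_Frozen):
    """One-off costs charged when a complication event occurs.

    ``source`` records whether the pair was supplied by the user
    (e.g., taken from the literature) or calibrated so that the cohort
    model reproduces published total-cost figures.  User-supplied costs
    must be non-negative; a calibrated pair is kept verbatim — including
    a negative component, which is a diagnostic that the cost structure
    implied by the calibration targets does not decompose into
    non-negative per-event prices under this model structure.
    """

    major_cost: float
    minor_cost: float
    source: Literal["user", "calibrated"] = "user"

    @model_validator(mode="after")
    def _user_nonnegative(self) -> "ComplicationEventCosts":
        if self.source == "user" and (self.major_cost < 0 or self.minor_cost < 0):
            raise ValueError("user-supplied complication costs must be >= 0")
        return self


class WageModel(_Frozen):
    """Hourly wage and missed-work durations behind indirect costs."""

    hourly_wage: float = Field(ge=0)
    hours_per_week: float = Field(default=40.0, gt=0)
    weeks_missed: dict[EpisodeKind, float] = Field(
        default_factory=lambda: {
            "operative": 8.0,
            "non_operative": 10.5,
            "rerupture_surgery": 8.0,
        }
    )

    @model_validator(mode="after")
    def _weeks_nonnegative(self) -> "WageModel":
        for kind in EPISODE_KINDS:
            if kind not in self.weeks_missed:
                raise ValueError(f"weeks_missed missing episode kind {kind!r}")
            if self.weeks_missed[kind] < 0:
                raise ValueError("weeks missed must be >= 0")
        return self


class UtilitySchedule(_Frozen):
    """Time-dependent utilities and complication decrements.

    ``recovery_utilities[k-1]`` is the utility during the k-th cycle
    since the most recent treatment; beyond the list the last entry
    applies.  Minor/major complications multiply the scheduled utility
    by their respective multipliers, either until the horizon
    (``decrement_duration="horizon"``, default) or for the single cycle
    after the event resolves (``"single_cycle"``).
    """

    recovery_utilities: tuple[float, ...] = (0.7, 0.8, 0.9)
    full_benefit_utility: float = Field(default=0.9, ge=0, le=1)
    minor_multiplier: float = Field(default=0.9, gt=0, le=1)
    major_multiplier: float = Field(default=0.8, gt=0, le=1)
    decrement_duration: Literal["horizon", "single_cycle"] = "horizon"

    @model_validator(mode="after")
    def _valid_schedule(self) -> "UtilitySchedule":
        if not self.recovery_utilities:
            raise ValueError("recovery_utilities must not be empty")
        for u in self.recovery_utilities:
            if not (0 <= u <= 1):
                raise ValueError("utilities must lie in [0, 1]")
        if any(
            b < a
            for a, b in zip(self.recovery_utilities, self.recovery_utilities[1:])
        ):
            raise ValueError("recovery_utilities must be non-decreasing")
        return self

    def utility(self, cycles_since_treatment: int) -> float:
        """Scheduled utility for the k-th cycle since treatment (k >= 1)."""
        k = max(1, int(cycles_since_treatment))
        idx = min(k, len(self.recovery_utilities)) - 1
        return self.recovery_utilities[idx]


class RunSettings(_Frozen):
    """Engine and analysis run configuration."""

    cycle_length: float = Field(default=0.25, gt=0)
    n_cycles: int = Field(default=8, ge=1)
    horizon: float = Field(default=2.0, gt=0)
    discount_rate: float = Field(default=0.0, ge=0)
    wtp_grid: tuple[float, ...] = (50_000.0, 100_000.0)
    psa_iterations: int = Field(default=10_000, ge=1)
    seed: int = 20140101

    @model_validator(mode="after")
    def _horizon_consistent(self) -> "RunSettings":
        if abs(self.n_cycles * self.cycle_length - self.horizon) > 1e-9:
            raise ValueError(
                f"n_cycles * cycle_length = {self.n_cycles * self.cycle_length} "
                f"must equal horizon = {self.horizon}"
            )
        return self


class ParameterSet(_Frozen):
    """Complete, internally consistent input set for the cohort model."""

    rates_nonoperative: EventRates
    relative_risks: dict[EventName, RelativeRisk]
    rates_operative: EventRates
    episode_costs: dict[EpisodeKind, EpisodeCosts]
    complication_costs: ComplicationEventCosts
    wage: WageModel
    utilities: UtilitySchedule
    # Optional arm-specific schedule for the non-operative strategy; when
    # None (the base case) both arms share ``utilities``.  Probabilistic
    # sensitivity analysis samples the two arms' schedules separately so
    # that relative quality of life — the model's dominant sensitivity —
    # is allowed to vary.
    utilities_nonoperative: Optional[UtilitySchedule] = None
    settings: RunSettings = RunSettings()
    # Proportional reduction applied to every utility accrued in the
    # non-operative strategy arm; the deterministic sensitivity analysis
    # sweeps this to find the quality-of-life tipping point.
    nonoperative_utility_penalty: float = Field(default=0.0, ge=0, lt=1)
    # When True, rates_operative must equal relative risk x non-operative rate.
    operative_rates_derived: bool = False

    @model_validator(mode="after")
    def _consistent(self) -> "ParameterSet":
        for ev in ("rerupture", "major_complication", "minor_complication"):
            if ev not in self.relative_risks:
                raise ValueError(f"relative_risks missing event {ev!r}")
            if self.relative_risks[ev].event != ev:
                raise ValueError(f"relative_risks[{ev!r}] describes the wrong event")
        for kind in EPISODE_KINDS:
            if kind not in self.episode_costs:
                raise ValueError(f"episode_costs missing kind {kind!r}")
            if self.episode_costs[kind].kind != kind:
                raise ValueError(f"episode_costs[{kind!r}] has mismatched kind")
        if self.operative_rates_derived:
            derived = derive_operative_rates(
                self.relative_risks, self.rates_nonoperative
            )
            for name in ("p_rerupture", "p_major", "p_minor"):
                if abs(getattr(derived, name) - getattr(self.rates_operative, name)) > 1e-9:
                    raise ValueError(
                        "operative_rates_derived is set but rates_operative "
                        f"disagree with RR x non-operative rates on {name}"
                    )
        return self


# ---------------------------------------------------------------------------
# Derivations the published tables imply
# ---------------------------------------------------------------------------

def derive_operative_rates(
    relative_risks: dict[EventName, RelativeRisk], nonoperative: EventRates
) -> EventRates:
    """Operative event rates as relative risk x non-operative rate.

    Each product is clipped into [0, 1].  Raises
    :class:`InvalidParameterError` if the derived rates leave no
    probability mass for the full-benefit outcome.
    """
    p_re = min(1.0, relative_risks["rerupture"].point * nonoperative.p_rerupture)
    p_maj = min(1.0, relative_risks["major_complication"].point * nonoperative.p_major)
    p_min = min(1.0, relative_risks["minor_complication"].point * nonoperative.p_minor)
    if p_re + p_maj + p_min >= 1:
        raise InvalidParameterError(
            f"derived operative rates sum to {p_re + p_maj + p_min:.4f} >= 1 "
            f"(rerupture={p_re:.4f}, major={p_maj:.4f}, minor={p_min:.4f})"
        )
    return EventRates(p_rerupture=p_re, p_major=p_maj, p_minor=p_min)


def episode_cost_total(costs: EpisodeCosts, include_missed_work: bool = True) -> float:
    """Total cost of one treatment episode.

    Sum of hospitalization, surgeon, physical therapy and (optionally)
    missed-work components.
    """
    total = costs.hospitalization + costs.surgeon + costs.physical_therapy
    if include_missed_work:
        total += costs.missed_work
    return total


def missed_work_cost(weeks: float, wage: WageModel) -> float:
    """Indirect cost of ``weeks`` of missed work under the wage model."""
    if weeks < 0:
        raise InvalidParameterError("weeks missed must be >= 0")
    return weeks * wage.hours_per_week * wage.hourly_wage


def implied_hourly_wage(
    missed_work_total: float, weeks: float, hours_per_week: float = 40.0
) -> float:
    """Hourly wage implied by a missed-work cost over a given duration."""
    if weeks <= 0 or hours_per_week <= 0:
        raise InvalidParameterError("weeks and hours_per_week must be positive")
    return missed_work_total / (weeks * hours_per_week)


# ---------------------------------------------------------------------------
# Calibration of the unpublished per-event complication costs
# ---------------------------------------------------------------------------

def calibrate_complication_costs(
    params: ParameterSet,
    target_total_operative: float,
    target_total_nonoperative: float,
    allow_negative: bool = False,
) -> ComplicationEventCosts:
    """Solve for per-event complication costs hitting published totals.

    Expected total cost is affine in the two unknown per-event costs, so
    the pair reproducing the two strategy totals solves a 2x2 linear
    system.  Coefficients are measured by running the cohort engine at
    unit major / unit minor / zero complication costs.

    Raises :class:`CalibrationError` when the system is singular, and —
    unless ``allow_negative`` is set — when a solved component is
    negative, which signals that the targets are inconsistent with a
    non-negative per-event price decomposition under the current model
    structure.  With ``allow_negative=True`` the exact algebraic
    solution is returned regardless of sign (never clipped), tagged
    ``source="calibrated"``.
    """
    import numpy as np

    from .engine import run_cohort  # deferred: calibration drives the engine

    def totals(major: float, minor: float) -> tuple[float, float]:
        probe = set_param(
            params,
            "complication_costs",
            ComplicationEventCosts(
                major_cost=major, minor_cost=minor, source="calibrated"
            ),
        )
        return (
            run_cohort("operative", probe).total_cost,
            run_cohort("non_operative", probe).total_cost,
        )

    base_op, base_non = totals(0.0, 0.0)
    maj_op, maj_non = totals(1.0, 0.0)
    min_op, min_non = totals(0.0, 1.0)

    coeff = np.array(
        [
            [maj_op - base_op, min_op - base_op],
            [maj_non - base_non, min_non - base_non],
        ]
    )
    rhs = np.array(
        [target_total_operative - base_op, target_total_nonoperative - base_non]
    )
    if abs(np.linalg.det(coeff)) < 1e-12:
        raise CalibrationError(
            "structure cannot be calibrated: complication incidences make the "
            "cost system singular"
        )
    major_cost, minor_cost = np.linalg.solve(coeff, rhs)
    if (major_cost < 0 or minor_cost < 0) and not allow_negative:
        raise CalibrationError(
            "calibration produced a negative per-event cost "
            f"(major={major_cost:.2f}, minor={minor_cost:.2f}): the targets are "
            "inconsistent with non-negative event prices under this model "
            "structure; pass allow_negative=True to keep the algebraic solution"
        )
    return ComplicationEventCosts(
        major_cost=float(major_cost), minor_cost=float(minor_cost), source="calibrated"
    )


class CalibrationError(RuntimeError):
    """The complication-cost calibration system has no acceptable solution."""


# ---------------------------------------------------------------------------
# Dotted-path access and the parameter-file dialect
# ---------------------------------------------------------------------------

def get_param(params: ParameterSet, path: str) -> float:
    """Read a scalar by dotted path, e.g. ``episode_costs.operative.hospitalization``."""
    obj: object = params
    for part in path.split("."):
        if isinstance(obj, dict):
            obj = obj[part]
        elif isinstance(obj, (list, tuple)):
            obj = obj[int(part)]
        else:
            obj = getattr(obj, part)
    return obj  # type: ignore[return-value]


def set_param(params: ParameterSet, path: str, value: object) -> ParameterSet:
    """Return a new :class:`ParameterSet` with one entry replaced.

    Setting anything under ``wage.`` recomputes every episode's
    missed-work cost from the wage model, keeping indirect costs
    consistent with the wage that generates them.
    """
    data = params.model_dump()
    node = data
    parts = path.split(".")
    for part in parts[:-1]:
        key = int(part) if isinstance(node, list) else part
        if isinstance(node[key], tuple):  # make nested tuples assignable
            node[key] = list(node[key])
        node = node[key]
    leaf = value.model_dump() if isinstance(value, BaseModel) else value
    if isinstance(node, list):
        node[int(parts[-1])] = leaf
    elif parts[-1] in node:
        node[parts[-1]] = leaf
    else:
        raise KeyError(f"unknown parameter path {path!r}")
    updated = ParameterSet.model_validate(data)
    if parts[0] == "wage":
        updated = rebuild_missed_work(updated)
    return updated


def rebuild_missed_work(params: ParameterSet) -> ParameterSet:
    """Recompute missed-work cost components from the wage model."""
    data = params.model_dump()
    for kind in EPISODE_KINDS:
        data["episode_costs"][kind]["missed_work"] = missed_work_cost(
            params.wage.weeks_missed[kind], params.wage
        )
    return ParameterSet.model_validate(data)


def save_params(params: ParameterSet, path: str) -> None:
    """Write a parameter file (YAML) mirroring the ParameterSet fields."""
    with open(path, "w") as fh:
        yaml.safe_dump(params.model_dump(mode="json"), fh, sort_keys=False)


def load_params(path: str) -> ParameterSet:
    """Load a parameter file written by :func:`save_params`."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    try:
        return ParameterSet.model_validate(data)
    except Exception as exc:  # surface field-level detail to the CLI
        raise InvalidParameterError(str(exc)) from exc
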