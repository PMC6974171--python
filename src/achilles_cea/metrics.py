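"""Cost-effectiveness comparison of two strategy outcomes.

Implements the standard decision rules of cost-utility analysis: the
incremental cost-effectiveness ratio (ICER = incremental cost /
incremental QALYs) with dominance classification, and the net monetary
benefit (NMB = willingness-to-pay x QALYs - cost).  A dominated
strategy — more costly and less effective — is excluded from ICER
reporting and labelled instead, matching standard reporting guidance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .engine import StrategyOutcome

_TIE_EPS = 1e-9

Classification = str  # reference_dominates | comparator_dominates | trade_off | equivalent


def nmb(outcome: StrategyOutcome, wtp: float) -> float:
    """Net monetary benefit of one strategy at willingness-to-pay ``wtp``."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * outcome.total_qalys - outcome.total_cost


@dataclass(frozen=True)
class ComparisonResult:
    """Incremental comparison of ``comparator`` against ``reference``.

    Deltas are comparator minus reference.  ``icer`` is defined only for
    genuine trade-offs (one strategy costlier but more effective);
    under dominance or equivalence it is ``None`` and the classification
    carries the verdict.  ``preferred`` maps each willingness-to-pay to
    the strategy with the higher net monetary benefit, ties resolving to
    the reference.
    """

    reference: str
    comparator: str
    delta_cost: float
    delta_qalys: float
    classification: Classification
    icer: Optional[float]
    nmb_difference: dict[float, float] = field(default_factory=dict)
    preferred: dict[float, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "comparator": self.comparator,
            "delta_cost": self.delta_cost,
            "delta_qalys": self.delta_qalys,
            "classification": self.classification,
            "icer": self.icer,
            "nmb_difference": {str(k): v for k, v in self.nmb_difference.items()},
            "preferred": {str(k): v for k, v in self.preferred.items()},
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def compare(
    reference: StrategyOutcome,
    comparator: StrategyOutcome,
    wtp_grid: Iterable[float] = (50_000.0, 100_000.0),
) -> ComparisonResult:
    """Incremental cost, incremental QALYs, ICER/dominance, NMB per WTP."""
    d_cost = comparator.total_cost - reference.total_cost
    d_q = comparator.total_qalys - reference.total_qalys

    if abs(d_cost) < _TIE_EPS and abs(d_q) < _TIE_EPS:
        classification, icer = "equivalent", None
    elif d_cost >= -_TIE_EPS and d_q <= _TIE_EPS:
        # comparator costs at least as much and yields no more benefit
        classification, icer = "reference_dominates", None
    elif d_cost <= _TIE_EPS and d_q >= -_TIE_EPS:
        classification, icer = "comparator_dominates", None
    else:
        classification, icer = "trade_off", d_cost / d_q

    nmb_diff: dict[float, float] = {}
    preferred: dict[float, str] = {}
    for wtp in wtp_grid:
        diff = wtp * d_q - d_cost  # NMB(comparator) - NMB(reference)
        nmb_diff[float(wtp)] = diff
        preferred[float(wtp)] = (
            comparator.strategy if diff > _TIE_EPS else reference.strategy
        )
    return ComparisonResult(
        reference=reference.strategy,
        comparator=comparator.strategy,
        delta_cost=d_cost,
        delta_qalys=d_q,
        classification=classification,
        icer=icer,
        nmb_difference=nmb_diff,
        preferred=preferred,
    )
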