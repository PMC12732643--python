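"""Pairwise cost-effectiveness statistics.

ICER = delta cost / delta QALYs; net monetary benefit at a willingness-to-pay
threshold lambda is lambda * dQ - dC.  Dominance flags replace the ratio when
it is not informative: "dominant" (cheaper or cost-neutral and more effective),
"dominated" (costlier or cost-neutral and less effective), "undefined" when
the QALY difference is exactly zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .outcomes import StrategyResult

__all__ = ["CEResult", "compute_icer", "compute_nmb", "compare_to_threshold", "compare"]

DOMINANT = "dominant"
DOMINATED = "dominated"
UNDEFINED = "undefined"


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of an intervention against a comparator."""

    intervention: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icer: Optional[float]
    dominance: Optional[str]
    threshold: float
    nmb_at_threshold: float

    @property
    def cost_effective(self) -> bool:
        return compare_to_threshold((self.icer, self.dominance), self.threshold)

    def as_dict(self) -> dict:
        return {
            "intervention": self.intervention,
            "comparator": self.comparator,
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "dominance": self.dominance,
            "threshold": self.threshold,
            "nmb_at_threshold": self.nmb_at_threshold,
            "cost_effective": self.cost_effective,
        }


def compute_icer(delta_cost: float, delta_qaly: float) -> tuple[Optional[float], Optional[str]]:
    """(icer, dominance flag).

    The ratio is reported whenever dQ != 0; the flag qualifies it.  dQ = 0
    yields no ratio and the "undefined" flag.
    """
    if not (math.isfinite(delta_cost) and math.isfinite(delta_qaly)):
        raise ValueError("delta_cost and delta_qaly must be finite")
    if delta_qaly == 0.0:
        return None, UNDEFINED
    icer = delta_cost / delta_qaly
    flag = None
    if delta_cost <= 0.0 and delta_qaly > 0.0:
        flag = DOMINANT
    elif delta_cost >= 0.0 and delta_qaly < 0.0:
        flag = DOMINATED
    return icer, flag


def compute_nmb(delta_cost: float, delta_qaly: float, threshold: float) -> float:
    """Net monetary benefit lambda * dQ - dC at willingness-to-pay lambda."""
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    return threshold * delta_qaly - delta_cost


def compare_to_threshold(icer_or_flag, threshold: float) -> bool:
    """Cost-effective iff dominant, or the ICER is at or below the threshold
    (inclusive boundary).  Dominated and undefined comparisons are not."""
    if isinstance(icer_or_flag, tuple):
        icer, flag = icer_or_flag
    elif isinstance(icer_or_flag, str):
        icer, flag = None, icer_or_flag
    else:
        icer, flag = icer_or_flag, None
    if flag == DOMINANT:
        return True
    if flag in (DOMINATED, UNDEFINED):
        return False
    return icer is not None and icer <= threshold


def compare(
    intervention: StrategyResult,
    comparator: StrategyResult,
    threshold: float,
) -> CEResult:
    """Full pairwise comparison of two strategy results."""
    dc = intervention.total_cost_discounted - comparator.total_cost_discounted
    dq = intervention.total_qaly_discounted - comparator.total_qaly_discounted
    icer, flag = compute_icer(dc, dq)
    return CEResult(
        intervention=intervention.strategy,
        comparator=comparator.strategy,
        delta_cost=dc,
        delta_qaly=dq,
        icer=icer,
        dominance=flag,
        threshold=threshold,
        nmb_at_threshold=compute_nmb(dc, dq, threshold),
    )
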