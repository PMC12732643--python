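"""Costs, utilities and discounted lifetime totals.

Utilities are linked to HAQ disability through a linear mapping
``u = intercept + slope * HAQ`` (slope < 0), clamped to [0, 1].  During
long-term extrapolation HAQ is floored at 1.5 (treated RA populations rarely
do better), which caps any state utility at ``u(1.5)``; trial utilities below
the cap are used as printed.  Costs are unit price x units-per-cycle, scaled
by the perspective's reimbursement fraction per cost category.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .parameters import ParameterSet, Settings

if TYPE_CHECKING:  # pragma: no cover
    from .markov_engine import CohortTrace

__all__ = [
    "Perspective",
    "StrategyResult",
    "haq_to_utility",
    "utility_to_haq",
    "apply_haq_floor",
    "floored_utility_and_haq",
    "cycle_cost",
    "accumulate_discounted",
    "perspectives_from",
    "load_perspectives",
    "HEALTHCARE_SYSTEM",
]


class Perspective(BaseModel):
    """Which fraction of each cost category a payer bears.

    The healthcare-system perspective carries every category in full; the
    patient out-of-pocket and insurance perspectives split it, category by
    category, so that their fractions sum to one.
    """

    name: str
    item_fractions: dict[str, float] = Field(default_factory=dict)
    default_fraction: float = 1.0

    @model_validator(mode="after")
    def _in_range(self) -> "Perspective":
        for cat, f in self.item_fractions.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{self.name}: fraction for {cat!r} = {f} outside [0, 1]")
        if not 0.0 <= self.default_fraction <= 1.0:
            raise ValueError(f"{self.name}: default fraction outside [0, 1]")
        return self

    def fraction(self, category: str) -> float:
        return self.item_fractions.get(category, self.default_fraction)


HEALTHCARE_SYSTEM = Perspective(name="healthcare_system", default_fraction=1.0)


def perspectives_from(params: ParameterSet) -> dict[str, Perspective]:
    """The three payer perspectives implied by the parameter file's
    reimbursement map: full system cost, the patient's share, and its
    complement borne by medical insurance."""
    out = {"healthcare_system": HEALTHCARE_SYSTEM}
    patient = params.reimbursement.get("patient_oop", {})
    out["patient_oop"] = Perspective(
        name="patient_oop", item_fractions=dict(patient), default_fraction=0.5
    )
    out["insurance"] = Perspective(
        name="insurance",
        item_fractions={k: 1.0 - v for k, v in patient.items()},
        default_fraction=0.5,
    )
    return out


def load_perspectives(path: str | Path) -> dict[str, Perspective]:
    payload = yaml.safe_load(Path(path).read_text())
    out = {}
    for name, spec in payload.items():
        out[name] = Perspective(
            name=name,
            item_fractions=spec.get("item_fractions", {}),
            default_fraction=spec.get("default_fraction", 1.0),
        )
    return out


# ---------------------------------------------------------------------------
# HAQ <-> utility


def haq_to_utility(haq, intercept: float, slope: float):
    """Linear HAQ->utility mapping, clamped to [0, 1]. ``slope`` < 0."""
    if slope >= 0:
        raise ValueError("slope must be negative (utility falls as HAQ rises)")
    return np.clip(intercept + slope * np.asarray(haq, dtype=float), 0.0, 1.0)


def utility_to_haq(utility, intercept: float, slope: float):
    """Inverse of the linear mapping (before clamping)."""
    if slope >= 0:
        raise ValueError("slope must be negative")
    return (np.asarray(utility, dtype=float) - intercept) / slope


def apply_haq_floor(haq, floor: float):
    """Long-term extrapolation floor: HAQ never falls below ``floor``."""
    if floor < 0:
        raise ValueError("floor must be nonnegative")
    return np.maximum(np.asarray(haq, dtype=float), floor)


def floored_utility_and_haq(utility, settings: Settings):
    """Resolve a trial utility into the (utility, HAQ) pair used in the model.

    The utility's HAQ equivalent is obtained by inverting the mapping and
    clipping to [floor, haq_max]; the floor binds on utility from above only:
    the effective utility is ``min(u, u(floor))`` and values below the cap are
    used as printed.
    """
    u = np.asarray(utility, dtype=float)
    cap = float(
        haq_to_utility(settings.haq_floor, settings.haq_map_intercept, settings.haq_map_slope)
    )
    haq_raw = utility_to_haq(u, settings.haq_map_intercept, settings.haq_map_slope)
    haq = np.clip(haq_raw, settings.haq_floor, settings.haq_max)
    u_eff = np.clip(np.minimum(u, cap), 0.0, 1.0)
    return u_eff, haq


# ---------------------------------------------------------------------------
# costs


def line_cycle_cost(
    cost_items: Sequence,
    params: ParameterSet,
    perspective: Perspective,
    values: Mapping[str, object] | None = None,
):
    """Six-month cost of one treatment line under a perspective.

    ``cost_items`` are (item-name, optional units-per-cycle) references from a
    strategy definition; ``values`` optionally overrides unit prices (scalars
    or arrays, e.g. PSA draws).
    """
    total = 0.0
    for use in cost_items:
        row = params.cost(use.item)  # fatal on a dangling reference
        units = row.units_per_cycle if use.units_per_cycle is None else use.units_per_cycle
        price = row.unit_price if values is None else values.get(use.item, row.unit_price)
        total = total + np.asarray(price, dtype=float) * units * perspective.fraction(row.category)
    return total


def cycle_cost(state_kind: str, line, params: ParameterSet, perspective: Perspective):
    """Per-cycle cost of one model state.

    ``line`` is the occupied treatment line (or the palliative line); the dead
    state accrues nothing.  Responders and non-responders on a line both carry
    the line's full cost (the non-responder cycle is the on-drug trial cycle).
    """
    if state_kind == "dead":
        return 0.0
    if line is None:
        raise ValueError(f"state {state_kind!r} needs a treatment line")
    return line_cycle_cost(line.costs, params, perspective)


# ---------------------------------------------------------------------------
# discounted totals


@dataclass(frozen=True)
class StrategyResult:
    """Lifetime discounted totals for one strategy under one perspective."""

    strategy: str
    perspective: str
    total_cost_discounted: float
    total_qaly_discounted: float
    trace: Optional["CohortTrace"] = None

    def as_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "perspective": self.perspective,
            "total_cost_discounted": self.total_cost_discounted,
            "total_qaly_discounted": self.total_qaly_discounted,
        }


def discount_weights(n_cycles: int, annual_rate: float, cycle_length_years: float) -> np.ndarray:
    """Per-cycle discount weights (1 + r)^(-k * cycle_length)."""
    if annual_rate < 0:
        raise ValueError("discount rate must be nonnegative")
    k = np.arange(n_cycles, dtype=float)
    return (1.0 + annual_rate) ** (-k * cycle_length_years)


def accumulate_discounted(
    trace: "CohortTrace",
    annual_rate: float | None = None,
    cycle_length_years: float | None = None,
) -> StrategyResult:
    """Sum a trace's per-cycle discounted increments into lifetime totals.

    The trace already carries discounted increments; passing an explicit rate
    re-discounts the stored undiscounted increments instead.
    """
    if annual_rate is None:
        cost = float(np.sum(trace.cycle_cost_discounted))
        qaly = float(np.sum(trace.cycle_qaly_discounted))
    else:
        cyc = trace.cycle_length_years if cycle_length_years is None else cycle_length_years
        w = discount_weights(len(trace.cycle_cost), annual_rate, cyc)
        cost = float(np.sum(trace.cycle_cost * w))
        qaly = float(np.sum(trace.cycle_qaly * w))
    return StrategyResult(
        strategy=trace.strategy_name,
        perspective=trace.perspective_name,
        total_cost_discounted=cost,
        total_qaly_discounted=qaly,
        trace=trace,
    )
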