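"""Deterministic sensitivity analyses: one-way (tornado) and scenarios.

One-way analysis re-runs the full model twice per parameter (at its lower and
upper bound, everything else at base) and records the ICER swing.  Scenarios
apply named overrides (values or multipliers), an alternative perspective,
and/or an alternative intervention pathway (e.g. combination first-line
therapy), then report the pairwise comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Optional, Union

import numpy as np
import yaml
from pydantic import BaseModel, Field

from . import cea
from .markov_engine import Strategy, load_strategy, run_strategy
from .outcomes import HEALTHCARE_SYSTEM, Perspective
from .parameters import LifeTable, ParameterSet, ProbabilityInput

logger = logging.getLogger(__name__)

__all__ = ["TornadoEntry", "ScenarioSpec", "run_one_way", "run_scenario", "load_scenario"]


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    icer_at_lower: float
    icer_at_upper: float
    error: Optional[str] = None

    @property
    def swing(self) -> float:
        if self.error:
            return float("nan")
        return abs(self.icer_at_upper - self.icer_at_lower)


def _icer_with_overrides(
    intervention: Strategy,
    comparator: Strategy,
    params: ParameterSet,
    life_table: LifeTable,
    threshold: float,
    perspective: Perspective,
    overrides: Mapping[str, object],
) -> cea.CEResult:
    res_i = run_strategy(intervention, params, life_table, perspective, overrides)
    res_c = run_strategy(comparator, params, life_table, perspective, overrides)
    return cea.compare(res_i, res_c, threshold)


def run_one_way(
    params: ParameterSet,
    intervention: Strategy,
    comparator: Strategy,
    life_table: LifeTable,
    threshold: float,
    perspective: Perspective = HEALTHCARE_SYSTEM,
    life_table_builder: Callable[[float], LifeTable] | None = None,
) -> list[TornadoEntry]:
    """One-way sensitivity over every parameter row, sorted by ICER swing.

    ``life_table_builder`` rebuilds the life table when the male-fraction row
    is varied; without it that row only enters through the (unchanged) table.
    A failed run flags its entry and the analysis continues.
    """
    entries: list[TornadoEntry] = []
    rows = [*params.probabilities, *params.costs, *params.utilities, *params.scalars]
    for row in rows:
        base = getattr(row, "base", None)
        if base is None:
            base = row.unit_price
        lo, hi = row.lower, row.upper
        icers = []
        err = None
        for bound in (lo, hi):
            try:
                lt = life_table
                if row.name == "Male (%)" and life_table_builder is not None:
                    lt = life_table_builder(bound)
                res = _icer_with_overrides(
                    intervention, comparator, params, lt, threshold, perspective,
                    {row.name: bound})
                icers.append(res.icer if res.icer is not None else float("nan"))
            except Exception as exc:  # noqa: BLE001 - flagged, analysis continues
                logger.warning("one-way run failed for %s at %s: %s", row.name, bound, exc)
                icers.append(float("nan"))
                err = str(exc)
        entries.append(TornadoEntry(row.name, icers[0], icers[1], err))
    entries.sort(key=lambda e: (-(e.swing if math.isfinite(e.swing) else -1.0), e.parameter))
    return entries


# ---------------------------------------------------------------------------
# scenarios


class ScenarioSpec(BaseModel):
    """A named what-if: parameter overrides, perspective, alternative pathway.

    Override values are either absolute replacements or ``{multiply: m}``
    multipliers on the base value (probabilities capped at 1).
    """

    name: str
    overrides: dict[str, Union[float, dict[str, float]]] = Field(default_factory=dict)
    perspective: Optional[str] = None
    intervention_strategy: Optional[str] = None  # path, resolved by the loader
    note: Optional[str] = None


def load_scenario(path: str | Path) -> tuple[ScenarioSpec, Optional[Strategy]]:
    """Read a scenario file; a relative intervention-strategy path is resolved
    against the scenario file's directory."""
    path = Path(path)
    spec = ScenarioSpec.model_validate(yaml.safe_load(path.read_text()))
    strategy = None
    if spec.intervention_strategy:
        ref = Path(spec.intervention_strategy)
        if not ref.is_absolute():
            ref = path.parent / ref
        strategy = load_strategy(ref)
    return spec, strategy


def resolve_overrides(spec: ScenarioSpec, params: ParameterSet) -> dict[str, float]:
    """Turn a scenario's overrides into absolute row values."""
    base = params.base_values()
    out: dict[str, float] = {}
    for name, val in spec.overrides.items():
        if name not in base:
            raise KeyError(f"scenario {spec.name!r}: unknown override target {name!r}")
        if isinstance(val, dict):
            if set(val) != {"multiply"}:
                raise ValueError(f"scenario {spec.name!r}: bad override for {name!r}")
            new = base[name] * val["multiply"]
            if isinstance(params.row(name), ProbabilityInput):
                new = min(new, 1.0)
            out[name] = new
        else:
            out[name] = float(val)
    return out


def run_scenario(
    spec: ScenarioSpec,
    params: ParameterSet,
    intervention: Strategy,
    comparator: Strategy,
    life_table: LifeTable,
    threshold: float,
    perspectives: Mapping[str, Perspective] | None = None,
    intervention_override: Strategy | None = None,
) -> cea.CEResult:
    """Pairwise comparison under a scenario's modifications."""
    overrides = resolve_overrides(spec, params)
    perspective = HEALTHCARE_SYSTEM
    if spec.perspective:
        if not perspectives or spec.perspective not in perspectives:
            raise KeyError(f"scenario {spec.name!r}: unknown perspective {spec.perspective!r}")
        perspective = perspectives[spec.perspective]
    strat_i = intervention_override or intervention
    return _icer_with_overrides(
        strat_i, comparator, params, life_table, threshold, perspective, overrides)
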