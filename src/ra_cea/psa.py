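"""Probabilistic sensitivity analysis.

Each iteration redraws every stochastic input from its fitted distribution
(Beta for rates at the source-window scale, Gamma for unit costs, Gamma
clamped to [0, 1] for utilities; draws are independent across rows), runs the
deterministic model on the draw, and stores per-strategy lifetime (cost,
QALY).  Summaries: the incremental cloud for the cost-effectiveness plane and
the acceptability curve (probability the intervention has the higher net
monetary benefit; ties favour the comparator).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .markov_engine import Strategy, run_totals
from .outcomes import HEALTHCARE_SYSTEM, Perspective
from .parameters import ParameterSet

__all__ = [
    "PSAResult",
    "sample_parameter_set",
    "run_psa",
    "compute_ceac",
    "fraction_cost_effective",
    "default_threshold_grid",
]


def _sample_rows(params: ParameterSet, rng: np.random.Generator, size) -> dict[str, np.ndarray]:
    """One draw (or an array of draws) for every stochastic row, keyed by name.

    Rates are sampled at the source-window scale (conversion to cycle
    probabilities happens downstream); utilities are clamped to [0, 1].
    Row order is fixed by the parameter file, so a seed pins every draw.
    """
    draws: dict[str, np.ndarray] = {}
    for row in params.probabilities:
        draws[row.name] = np.clip(row.fit().sample(rng, size), 0.0, 1.0)
    for row in params.costs:
        draws[row.name] = row.fit().sample(rng, size)
    for row in params.utilities:
        draws[row.name] = np.clip(row.fit().sample(rng, size), 0.0, 1.0)
    return draws


def sample_parameter_set(params: ParameterSet, rng_seed: int) -> ParameterSet:
    """A single PSA draw as a full parameter set (deterministic in the seed)."""
    rng = np.random.default_rng(rng_seed)
    draws = _sample_rows(params, rng, size=())
    updated = params.model_copy(deep=True)
    for row in updated.probabilities:
        row.base = float(draws[row.name])
    for row in updated.costs:
        row.unit_price = float(np.clip(draws[row.name], row.lower * 0, None))
    for row in updated.utilities:
        row.base = float(draws[row.name])
    return updated


@dataclass
class PSAResult:
    """Per-iteration lifetime outcomes for two strategies."""

    intervention: str
    comparator: str
    seed: int
    n_iterations: int
    n_failed: int
    cost: dict[str, np.ndarray]  # strategy -> (n,)
    qaly: dict[str, np.ndarray]

    @property
    def delta_cost(self) -> np.ndarray:
        return self.cost[self.intervention] - self.cost[self.comparator]

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.qaly[self.intervention] - self.qaly[self.comparator]

    def cloud_frame(self) -> pd.DataFrame:
        frames = []
        for name in (self.comparator, self.intervention):
            frames.append(pd.DataFrame({
                "iteration": np.arange(self.n_iterations),
                "strategy": name,
                "cost": self.cost[name],
                "qaly": self.qaly[name],
            }))
        return pd.concat(frames, ignore_index=True)


def run_psa(
    params: ParameterSet,
    intervention: Strategy,
    comparator: Strategy,
    life_table,
    n_iter: int,
    seed: int,
    perspective: Perspective = HEALTHCARE_SYSTEM,
) -> PSAResult:
    """Monte-Carlo parameter uncertainty propagated to lifetime outcomes.

    Both strategies are run on the same draw in each iteration.  Iterations
    with non-finite outcomes are excluded and counted.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    draws = _sample_rows(params, rng, size=(n_iter,))
    cost: dict[str, np.ndarray] = {}
    qaly: dict[str, np.ndarray] = {}
    for strat in (comparator, intervention):
        c, q = run_totals(strat, params, life_table, perspective, overrides=draws)
        cost[strat.name] = np.asarray(c, dtype=float)
        qaly[strat.name] = np.asarray(q, dtype=float)
    ok = np.ones(n_iter, dtype=bool)
    for arr in (*cost.values(), *qaly.values()):
        ok &= np.isfinite(arr)
    n_failed = int(n_iter - ok.sum())
    if n_failed:
        cost = {k: v[ok] for k, v in cost.items()}
        qaly = {k: v[ok] for k, v in qaly.items()}
    return PSAResult(
        intervention=intervention.name,
        comparator=comparator.name,
        seed=seed,
        n_iterations=int(ok.sum()),
        n_failed=n_failed,
        cost=cost,
        qaly=qaly,
    )


def default_threshold_grid(gdp_per_capita: float = 95749.0, step: float = 500.0) -> np.ndarray:
    """0 to 3x GDP per capita in fixed steps (covers the usual decision range)."""
    return np.arange(0.0, 3.0 * gdp_per_capita + step, step)


def compute_ceac(psa: PSAResult, thresholds: Sequence[float]) -> pd.DataFrame:
    """P(intervention has the higher net monetary benefit) per threshold.

    Ties in NMB count for the comparator (conservative; measure-zero for
    continuous draws).
    """
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.size == 0:
        raise ValueError("threshold grid must be non-empty")
    dq = psa.delta_qaly
    dc = psa.delta_cost
    nmb = thresholds[:, None] * dq[None, :] - dc[None, :]
    prob = (nmb > 0.0).mean(axis=1)
    return pd.DataFrame({"threshold": thresholds, "probability": prob})


def fraction_cost_effective(psa: PSAResult, threshold: float) -> float:
    """Fraction of iterations where the intervention's NMB beats the
    comparator's at a single willingness-to-pay threshold."""
    return float((threshold * psa.delta_qaly - psa.delta_cost > 0.0).mean())
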