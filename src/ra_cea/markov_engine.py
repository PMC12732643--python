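"""Sequential-treatment Markov cohort engine.

A strategy is an ordered list of treatment lines ending in palliative care.
The cohort enters line 1 at model start and is split once, at line entry,
into responders and non-responders (trials report response at a single
landmark).  Responders stay on the line and face a per-cycle withdrawal
probability; non-responders spend their single on-drug trial cycle on the
line and then move on.  Withdrawers and non-responders enter the next line
(no standalone "discontinued" dwell state); the last active line feeds
palliative care, which absorbs until death.  Death competes with every
transition: background mortality is applied first each cycle, then
response/withdrawal among survivors.  Mortality follows an age-indexed life
table adjusted on the hazard scale by a HAQ-dependent hazard ratio.  No
half-cycle correction is applied; each cycle accrues start-of-cycle
occupancy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from . import outcomes
from .parameters import LifeTable, ParameterSet, Settings, rate_to_cycle_prob

__all__ = [
    "CostUse",
    "TreatmentLine",
    "PalliativeLine",
    "Strategy",
    "ModelState",
    "CohortTrace",
    "Dynamics",
    "load_strategy",
    "resolve_dynamics",
    "background_mortality_prob",
    "build_cycle_update",
    "run_cohort_trace",
    "run_strategy",
    "run_totals",
]


# ---------------------------------------------------------------------------
# strategy definition


class CostUse(BaseModel):
    """Reference to a cost row, optionally overriding its usage per cycle."""

    item: str
    units_per_cycle: Optional[float] = Field(default=None, ge=0.0)


class TreatmentLine(BaseModel):
    """One active line of therapy in a sequential strategy."""

    name: str
    response: str  # probability row: landmark response rate
    withdrawal: str  # probability row: per-window withdrawal rate
    utility_responder: str
    utility_nonresponder: str = "u base"
    costs: list[CostUse] = Field(default_factory=list)
    haq_responder: Optional[float] = None  # override; default derived from utility


class PalliativeLine(BaseModel):
    """Terminal palliative-care line: absorbing until death."""

    name: str = "Palliative care"
    utility: str = "u Palliative care"
    costs: list[CostUse] = Field(default_factory=list)
    haq: Optional[float] = None


class Strategy(BaseModel):
    """Ordered treatment pathway: active lines, then palliative care."""

    name: str
    lines: list[TreatmentLine] = Field(min_length=1)
    palliative: PalliativeLine = Field(default_factory=PalliativeLine)

    @property
    def n_lines(self) -> int:
        return len(self.lines)


def load_strategy(path: str | Path) -> Strategy:
    payload = yaml.safe_load(Path(path).read_text())
    return Strategy.model_validate(payload)


# ---------------------------------------------------------------------------
# states


@dataclass(frozen=True)
class ModelState:
    kind: Literal["on_line_responder", "on_line_nonresponder", "palliative", "dead"]
    line_index: Optional[int] = None

    def label(self) -> str:
        if self.kind == "on_line_responder":
            return f"line{self.line_index}_responder"
        if self.kind == "on_line_nonresponder":
            return f"line{self.line_index}_nonresponder"
        return self.kind


def state_space(strategy: Strategy) -> list[ModelState]:
    """State order: (responder, non-responder) per line, palliative, dead."""
    states: list[ModelState] = []
    for i in range(strategy.n_lines):
        states.append(ModelState("on_line_responder", i))
        states.append(ModelState("on_line_nonresponder", i))
    states.append(ModelState("palliative"))
    states.append(ModelState("dead"))
    return states


# ---------------------------------------------------------------------------
# mortality


def background_mortality_prob(
    age: float,
    haq: float,
    life_table: LifeTable,
    hr_per_haq: float,
    cycle_length_years: float = 0.5,
):
    """Cycle death probability at ``age`` for a patient with disability ``haq``.

    The annual life-table probability is adjusted on the hazard scale,
    ``q_adj = 1 - (1 - qx) ** (hr ** haq)``, then converted to the cycle
    length under a constant hazard.
    """
    qx = life_table.annual_qx(age)
    m = np.power(hr_per_haq, np.asarray(haq, dtype=float))
    out = -np.expm1(m * cycle_length_years * np.log1p(-qx))
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# resolved dynamics


@dataclass
class Dynamics:
    """Strategy dynamics resolved to numeric arrays.

    Every per-line array has shape ``batch + (L,)``; palliative entries have
    shape ``batch``.  A batch dimension carries PSA draws.
    """

    strategy_name: str
    perspective_name: str
    response: np.ndarray
    withdrawal: np.ndarray
    cost_line: np.ndarray
    u_resp: np.ndarray
    u_nonresp: np.ndarray
    haq_resp: np.ndarray
    haq_nonresp: np.ndarray
    pall_cost: np.ndarray
    pall_u: np.ndarray
    pall_haq: np.ndarray
    settings: Settings

    @property
    def n_lines(self) -> int:
        return self.response.shape[-1]

    @property
    def batch_shape(self) -> tuple:
        return self.response.shape[:-1]


def _as_prob(x, what: str):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError(f"{what} outside [0, 1]")
    return x


def resolve_dynamics(
    strategy: Strategy,
    params: ParameterSet,
    perspective: outcomes.Perspective = outcomes.HEALTHCARE_SYSTEM,
    overrides: Mapping[str, object] | None = None,
) -> Dynamics:
    """Resolve a strategy against a parameter set into numeric dynamics.

    ``overrides`` replaces row base values by name (scalars, or arrays of PSA
    draws at the source-window scale for rates and at the printed scale for
    prices/utilities).
    """
    settings = params.effective_settings(overrides)
    values: dict[str, object] = dict(params.base_values())
    if overrides:
        for name, val in overrides.items():
            if name in values:
                values[name] = val
    cycle_months = settings.cycle_length_years * 12.0

    resp, wdr, cost, u_r, u_n, h_r, h_n = [], [], [], [], [], [], []
    for line in strategy.lines:
        r_row = params.probability(line.response)
        w_row = params.probability(line.withdrawal)
        resp.append(rate_to_cycle_prob(
            _as_prob(values[r_row.name], r_row.name), r_row.window_months, cycle_months))
        wdr.append(rate_to_cycle_prob(
            _as_prob(values[w_row.name], w_row.name), w_row.window_months, cycle_months))
        u_raw = np.clip(np.asarray(values[params.utility(line.utility_responder).name],
                                   dtype=float), 0.0, 1.0)
        ur, hr_ = outcomes.floored_utility_and_haq(u_raw, settings)
        if line.haq_responder is not None:
            hr_ = np.broadcast_to(
                outcomes.apply_haq_floor(line.haq_responder, settings.haq_floor), ur.shape)
        un_raw = np.clip(np.asarray(values[params.utility(line.utility_nonresponder).name],
                                    dtype=float), 0.0, 1.0)
        un, hn = outcomes.floored_utility_and_haq(un_raw, settings)
        u_r.append(ur); h_r.append(hr_); u_n.append(un); h_n.append(hn)
        cost.append(outcomes.line_cycle_cost(line.costs, params, perspective, values))

    pal = strategy.palliative
    pu_raw = np.clip(np.asarray(values[params.utility(pal.utility).name], dtype=float), 0.0, 1.0)
    pall_u, pall_haq = outcomes.floored_utility_and_haq(pu_raw, settings)
    if pal.haq is not None:
        pall_haq = np.broadcast_to(
            outcomes.apply_haq_floor(pal.haq, settings.haq_floor), pall_u.shape)
    pall_cost = np.asarray(
        outcomes.line_cycle_cost(pal.costs, params, perspective, values), dtype=float)

    stacked = [np.stack(np.broadcast_arrays(*group), axis=-1)
               for group in (resp, wdr, cost, u_r, u_n, h_r, h_n)]
    batch = np.broadcast_shapes(*(a.shape[:-1] for a in stacked),
                                pall_cost.shape, pall_u.shape, pall_haq.shape)
    stacked = [np.broadcast_to(a, batch + a.shape[-1:]).astype(float) for a in stacked]
    return Dynamics(
        strategy_name=strategy.name,
        perspective_name=perspective.name,
        response=stacked[0], withdrawal=stacked[1], cost_line=stacked[2],
        u_resp=stacked[3], u_nonresp=stacked[4], haq_resp=stacked[5], haq_nonresp=stacked[6],
        pall_cost=np.broadcast_to(np.asarray(pall_cost, float), batch),
        pall_u=np.broadcast_to(np.asarray(pall_u, float), batch),
        pall_haq=np.broadcast_to(np.asarray(pall_haq, float), batch),
        settings=settings,
    )


# ---------------------------------------------------------------------------
# cohort iteration


@dataclass
class CohortTrace:
    """Per-cycle occupancy and accrued increments for one strategy."""

    strategy_name: str
    perspective_name: str
    states: list[ModelState]
    occupancy: np.ndarray  # (K + 1, S): start-of-cycle rows plus final state
    cycle_cost: np.ndarray  # (K,), undiscounted CNY
    cycle_qaly: np.ndarray  # (K,), undiscounted QALYs
    cycle_cost_discounted: np.ndarray
    cycle_qaly_discounted: np.ndarray
    start_age: float
    cycle_length_years: float

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_cost)

    def line_occupancy(self, line_index: int) -> np.ndarray:
        """Fraction of the cohort on a given line (responders + non-responders)
        at the start of each cycle."""
        return self.occupancy[:, 2 * line_index] + self.occupancy[:, 2 * line_index + 1]

    @property
    def dead_fraction(self) -> np.ndarray:
        return self.occupancy[:, -1]


def _death_probs(dyn: Dynamics, life_table: LifeTable, hr: float):
    """Pre-computed hazard multipliers per state (HAQ constant over cycles)."""
    return (
        np.power(hr, dyn.haq_resp),
        np.power(hr, dyn.haq_nonresp),
        np.power(hr, dyn.pall_haq),
    )


def _iterate(dyn: Dynamics, life_table: LifeTable, record_trace: bool):
    s = dyn.settings
    K = s.n_cycles
    L = dyn.n_lines
    batch = dyn.batch_shape
    cyc = s.cycle_length_years
    disc = s.discount_rate_annual

    resp = np.zeros(batch + (L,))
    nonresp = np.zeros(batch + (L,))
    resp[..., 0] = dyn.response[..., 0]
    nonresp[..., 0] = 1.0 - dyn.response[..., 0]
    pall = np.zeros(batch)
    dead = np.zeros(batch)

    m_resp, m_nr, m_pall = _death_probs(dyn, life_table, s.mortality_haq_hr)

    cost_total = np.zeros(batch)
    qaly_total = np.zeros(batch)
    occupancy = np.zeros((K + 1, 2 * L + 2)) if record_trace else None
    inc_cost = np.zeros(K) if record_trace else None
    inc_qaly = np.zeros(K) if record_trace else None
    inc_cost_d = np.zeros(K) if record_trace else None
    inc_qaly_d = np.zeros(K) if record_trace else None

    def snapshot(row):
        occupancy[row, 0:2 * L:2] = resp
        occupancy[row, 1:2 * L:2] = nonresp
        occupancy[row, 2 * L] = pall
        occupancy[row, 2 * L + 1] = dead

    for k in range(K):
        if record_trace:
            snapshot(k)
        w = (1.0 + disc) ** (-k * cyc)
        cost_k = np.sum((resp + nonresp) * dyn.cost_line, axis=-1) + pall * dyn.pall_cost
        qaly_k = (np.sum(resp * dyn.u_resp + nonresp * dyn.u_nonresp, axis=-1)
                  + pall * dyn.pall_u) * cyc
        cost_total = cost_total + w * cost_k
        qaly_total = qaly_total + w * qaly_k
        if record_trace:
            inc_cost[k] = cost_k
            inc_qaly[k] = qaly_k
            inc_cost_d[k] = w * cost_k
            inc_qaly_d[k] = w * qaly_k

        age = s.start_age + k * cyc
        logp = np.log1p(-life_table.annual_qx(age))
        d_resp = -np.expm1(m_resp * cyc * logp)
        d_nr = -np.expm1(m_nr * cyc * logp)
        d_pall = -np.expm1(m_pall * cyc * logp)

        dead = dead + np.sum(resp * d_resp + nonresp * d_nr, axis=-1) + pall * d_pall
        leavers = resp * (1.0 - d_resp) * dyn.withdrawal + nonresp * (1.0 - d_nr)
        new_resp = resp * (1.0 - d_resp) * (1.0 - dyn.withdrawal)
        new_nonresp = np.zeros_like(nonresp)
        entrants = leavers[..., : L - 1]
        new_resp[..., 1:] = new_resp[..., 1:] + entrants * dyn.response[..., 1:]
        new_nonresp[..., 1:] = entrants * (1.0 - dyn.response[..., 1:])
        pall = pall * (1.0 - d_pall) + leavers[..., L - 1]
        resp, nonresp = new_resp, new_nonresp

    if record_trace:
        snapshot(K)
    return cost_total, qaly_total, occupancy, (inc_cost, inc_qaly, inc_cost_d, inc_qaly_d)


def run_cohort_trace(
    strategy: Strategy,
    params: ParameterSet,
    life_table: LifeTable,
    perspective: outcomes.Perspective = outcomes.HEALTHCARE_SYSTEM,
    overrides: Mapping[str, object] | None = None,
) -> CohortTrace:
    """Run the cohort from 100% entering line 1 to death or the age cap."""
    dyn = resolve_dynamics(strategy, params, perspective, overrides)
    if dyn.batch_shape != ():
        raise ValueError("run_cohort_trace needs scalar inputs; use run_totals for batches")
    _, _, occupancy, (ic, iq, icd, iqd) = _iterate(dyn, life_table, record_trace=True)
    return CohortTrace(
        strategy_name=strategy.name,
        perspective_name=perspective.name,
        states=state_space(strategy),
        occupancy=occupancy,
        cycle_cost=ic,
        cycle_qaly=iq,
        cycle_cost_discounted=icd,
        cycle_qaly_discounted=iqd,
        start_age=dyn.settings.start_age,
        cycle_length_years=dyn.settings.cycle_length_years,
    )


def run_strategy(
    strategy: Strategy,
    params: ParameterSet,
    life_table: LifeTable,
    perspective: outcomes.Perspective = outcomes.HEALTHCARE_SYSTEM,
    overrides: Mapping[str, object] | None = None,
) -> outcomes.StrategyResult:
    trace = run_cohort_trace(strategy, params, life_table, perspective, overrides)
    return outcomes.accumulate_discounted(trace)


def run_totals(
    strategy: Strategy,
    params: ParameterSet,
    life_table: LifeTable,
    perspective: outcomes.Perspective = outcomes.HEALTHCARE_SYSTEM,
    overrides: Mapping[str, object] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Lifetime discounted (cost, QALY) totals; supports batched overrides."""
    dyn = resolve_dynamics(strategy, params, perspective, overrides)
    cost, qaly, _, _ = _iterate(dyn, life_table, record_trace=False)
    return cost, qaly


# ---------------------------------------------------------------------------
# explicit transition operator (cross-check surface)


def build_cycle_update(
    strategy: Strategy,
    cycle: int,
    params: ParameterSet,
    life_table: LifeTable,
    overrides: Mapping[str, object] | None = None,
) -> np.ndarray:
    """Dense stochastic transition matrix for one cycle.

    Row/column order follows :func:`state_space`.  Built independently of the
    vectorized cohort kernel so the two constructions can cross-check each
    other; every row sums to one by construction and is validated.
    """
    dyn = resolve_dynamics(strategy, params, overrides=overrides)
    if dyn.batch_shape != ():
        raise ValueError("build_cycle_update needs scalar inputs")
    s = dyn.settings
    if cycle > s.n_cycles:
        raise ValueError(f"cycle {cycle} beyond horizon {s.n_cycles}")
    L = dyn.n_lines
    S = 2 * L + 2
    PALL, DEAD = 2 * L, 2 * L + 1
    age = s.start_age + cycle * s.cycle_length_years
    M = np.zeros((S, S))
    hr = s.mortality_haq_hr

    def dest(i_next: int, mass: float, row: np.ndarray):
        """Split entrants to line i_next by its landmark response."""
        if i_next < L:
            r = dyn.response[i_next]
            row[2 * i_next] += mass * r
            row[2 * i_next + 1] += mass * (1.0 - r)
        else:
            row[PALL] += mass

    for i in range(L):
        w = float(dyn.withdrawal[i])
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"withdrawal probability for line {i} outside [0, 1]")
        d_r = background_mortality_prob(age, dyn.haq_resp[i], life_table, hr, s.cycle_length_years)
        d_n = background_mortality_prob(age, dyn.haq_nonresp[i], life_table, hr,
                                        s.cycle_length_years)
        row = M[2 * i]
        row[DEAD] = d_r
        row[2 * i] = (1.0 - d_r) * (1.0 - w)
        dest(i + 1, (1.0 - d_r) * w, row)
        row = M[2 * i + 1]
        row[DEAD] = d_n
        dest(i + 1, 1.0 - d_n, row)

    d_p = background_mortality_prob(age, dyn.pall_haq, life_table, hr, s.cycle_length_years)
    M[PALL, PALL] = 1.0 - d_p
    M[PALL, DEAD] = d_p
    M[DEAD, DEAD] = 1.0

    sums = M.sum(axis=1)
    bad = np.where(np.abs(sums - 1.0) > 1e-9)[0]
    if bad.size:
        labels = [st.label() for st in np.asarray(state_space(strategy), dtype=object)[bad]]
        raise ValueError(f"transition rows do not sum to 1 for states {labels}")
    return M
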