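"""Synthetic inputs: life tables, trial-like datasets, and a patient-level
microsimulation oracle.

No public life table is bundled; a Gompertz-Makeham generator stands in.  Its
coefficients are configuration: the defaults trace a plausible East-Asian
mortality curve and are never claimed to reproduce any national table.  The
trial generator emulates a two-arm randomized comparison with nested
ACR20/50/70 response indicators and withdrawal events.  The microsimulation
replays the cohort engine's per-cycle probabilities patient by patient and is
the engine's independent validation oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import outcomes
from .markov_engine import Dynamics, Strategy, resolve_dynamics
from .parameters import LifeTable, ParameterSet

__all__ = [
    "GompertzMakehamCoefficients",
    "DEFAULT_FEMALE_COEFFS",
    "DEFAULT_MALE_COEFFS",
    "SyntheticTrial",
    "generate_life_table",
    "blended_life_table",
    "generate_trial",
    "microsim_oracle",
    "MicrosimResult",
]


# ---------------------------------------------------------------------------
# life table


@dataclass(frozen=True)
class GompertzMakehamCoefficients:
    """Hazard mu(x) = makeham + gompertz_b * exp(gompertz_c * x)."""

    makeham: float
    gompertz_b: float
    gompertz_c: float

    def hazard(self, age) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        return self.makeham + self.gompertz_b * np.exp(self.gompertz_c * age)


# Plausible East-Asian all-cause schedules (configuration, not a national table).
DEFAULT_FEMALE_COEFFS = GompertzMakehamCoefficients(1.0e-4, 1.44e-5, 0.0997)
DEFAULT_MALE_COEFFS = GompertzMakehamCoefficients(2.0e-4, 4.86e-5, 0.090)


def generate_life_table(
    coefficients: GompertzMakehamCoefficients = DEFAULT_FEMALE_COEFFS,
    max_age: int = 110,
) -> LifeTable:
    """Deterministic synthetic life table: qx = 1 - exp(-integrated hazard).

    The hazard is integrated exactly over each 1-year age interval.  Fails if
    any qx reaches 1 before ``max_age`` (coefficients too aggressive).
    """
    if coefficients.makeham < 0 or coefficients.gompertz_b <= 0 or coefficients.gompertz_c <= 0:
        raise ValueError("coefficients must be positive")
    ages = np.arange(0, max_age + 1)
    c = coefficients.gompertz_c
    cumhaz = (coefficients.makeham
              + coefficients.gompertz_b / c * np.exp(c * ages) * (np.exp(c) - 1.0))
    qx = -np.expm1(-cumhaz)
    if np.any(qx >= 1.0):
        raise ValueError("coefficients too aggressive: qx reaches 1 before max_age")
    return LifeTable(ages=ages, qx=qx)


def blended_life_table(
    male_fraction: float,
    female: GompertzMakehamCoefficients = DEFAULT_FEMALE_COEFFS,
    male: GompertzMakehamCoefficients = DEFAULT_MALE_COEFFS,
    max_age: int = 110,
) -> LifeTable:
    """Cohort life table: sex-specific qx mixed by the male fraction."""
    if not 0.0 <= male_fraction <= 1.0:
        raise ValueError("male_fraction must be in [0, 1]")
    f = generate_life_table(female, max_age)
    m = generate_life_table(male, max_age)
    return LifeTable(ages=f.ages, qx=(1.0 - male_fraction) * f.qx + male_fraction * m.qx)


def life_expectancy(table: LifeTable, age: int) -> float:
    """Curtate-plus-half life expectancy from ``age`` (years)."""
    qx = table.qx[age - int(table.ages[0]):]
    surv = np.cumprod(1.0 - qx)
    return float(np.sum(surv)) + 0.5


# ---------------------------------------------------------------------------
# synthetic trial


@dataclass(frozen=True)
class SyntheticTrial:
    """Two-arm patient-level trial with nested ACR responses."""

    data: pd.DataFrame  # patient_id, arm, acr20, acr50, acr70, withdrew
    seed: int

    def summary(self) -> pd.DataFrame:
        return self.data.groupby("arm")[["acr20", "acr50", "acr70", "withdrew"]].mean()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def generate_trial(
    n_per_arm: Mapping[str, int],
    true_rates: Mapping[str, Sequence[float]],
    seed: int,
    withdrawal_rates: Mapping[str, float] | None = None,
) -> SyntheticTrial:
    """Simulate per-patient ACR20/50/70 and withdrawal indicators.

    ``true_rates[arm]`` is (ACR20, ACR50, ACR70), which must be non-increasing:
    the thresholds are nested, so ACR50 responders are drawn by thinning ACR20
    responders and ACR70 by thinning ACR50.
    """
    rng = np.random.default_rng(seed)
    frames = []
    offset = 0
    for arm, n in n_per_arm.items():
        p20, p50, p70 = true_rates[arm]
        if not (1.0 >= p20 >= p50 >= p70 >= 0.0):
            raise ValueError(f"{arm}: rates must satisfy ACR20 >= ACR50 >= ACR70")
        acr20 = rng.random(n) < p20
        acr50 = acr20 & (rng.random(n) < (p50 / p20 if p20 > 0 else 0.0))
        acr70 = acr50 & (rng.random(n) < (p70 / p50 if p50 > 0 else 0.0))
        w = withdrawal_rates.get(arm, 0.0) if withdrawal_rates else 0.0
        withdrew = rng.random(n) < w
        frames.append(pd.DataFrame({
            "patient_id": np.arange(offset, offset + n),
            "arm": arm,
            "acr20": acr20.astype(int),
            "acr50": acr50.astype(int),
            "acr70": acr70.astype(int),
            "withdrew": withdrew.astype(int),
        }))
        offset += n
    return SyntheticTrial(data=pd.concat(frames, ignore_index=True), seed=seed)


# ---------------------------------------------------------------------------
# microsimulation oracle


@dataclass(frozen=True)
class MicrosimResult:
    n_patients: int
    mean_cost: float
    mean_qaly: float
    se_cost: float
    se_qaly: float


def microsim_oracle(
    strategy: Strategy,
    params: ParameterSet,
    life_table: LifeTable,
    n_patients: int,
    seed: int,
    perspective: outcomes.Perspective = outcomes.HEALTHCARE_SYSTEM,
    overrides: Mapping[str, object] | None = None,
) -> MicrosimResult:
    """Patient-level replay of the cohort model.

    Each patient walks the same states with the same per-cycle probabilities,
    event ordering (death first, then withdrawal/response among survivors),
    HAQ floor and discounting as the cohort engine; accrual uses
    start-of-cycle state.  Returns Monte-Carlo means and standard errors of
    discounted lifetime cost and QALYs.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    dyn = resolve_dynamics(strategy, params, perspective, overrides)
    if dyn.batch_shape != ():
        raise ValueError("microsim_oracle needs scalar inputs")
    s = dyn.settings
    L = dyn.n_lines
    K = s.n_cycles
    cyc = s.cycle_length_years
    PALL, DEAD = 2 * L, 2 * L + 1

    # per-state lookup vectors, order: resp_0, nr_0, ..., palliative, dead
    state_cost = np.zeros(2 * L + 2)
    state_util = np.zeros(2 * L + 2)
    state_mult = np.ones(2 * L + 2)  # HAQ hazard multiplier
    hr = s.mortality_haq_hr
    state_cost[0:2 * L:2] = dyn.cost_line
    state_cost[1:2 * L:2] = dyn.cost_line
    state_util[0:2 * L:2] = dyn.u_resp
    state_util[1:2 * L:2] = dyn.u_nonresp
    state_mult[0:2 * L:2] = hr ** dyn.haq_resp
    state_mult[1:2 * L:2] = hr ** dyn.haq_nonresp
    state_cost[PALL] = dyn.pall_cost
    state_util[PALL] = dyn.pall_u
    state_mult[PALL] = hr ** dyn.pall_haq

    rng = np.random.default_rng(seed)
    state = np.where(rng.random(n_patients) < dyn.response[0], 0, 1)
    cost = np.zeros(n_patients)
    qaly = np.zeros(n_patients)

    for k in range(K):
        w = (1.0 + s.discount_rate_annual) ** (-k * cyc)
        cost += w * state_cost[state]
        qaly += w * state_util[state] * cyc
        alive = state != DEAD
        age = s.start_age + k * cyc
        logp = np.log1p(-life_table.annual_qx(age))
        d = -np.expm1(state_mult[state] * cyc * logp)
        dies = alive & (rng.random(n_patients) < d)
        state = np.where(dies, DEAD, state)
        # survivors: withdrawal among responders, pass-through for non-responders
        u_move = rng.random(n_patients)
        u_split = rng.random(n_patients)
        new_state = state.copy()
        for i in range(L):
            on_resp = state == 2 * i
            on_nr = state == 2 * i + 1
            moving = (on_resp & (u_move < dyn.withdrawal[i])) | on_nr
            if i + 1 < L:
                responds = u_split < dyn.response[i + 1]
                new_state = np.where(moving & responds, 2 * (i + 1), new_state)
                new_state = np.where(moving & ~responds, 2 * (i + 1) + 1, new_state)
            else:
                new_state = np.where(moving, PALL, new_state)
        state = new_state

    return MicrosimResult(
        n_patients=n_patients,
        mean_cost=float(cost.mean()),
        mean_qaly=float(qaly.mean()),
        se_cost=float(cost.std(ddof=1) / np.sqrt(n_patients)) if n_patients > 1 else 0.0,
        se_qaly=float(qaly.std(ddof=1) / np.sqrt(n_patients)) if n_patients > 1 else 0.0,
    )
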