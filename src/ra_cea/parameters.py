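"""Model inputs: parameter-file parsing, rate conversion, PSA distribution fitting.

Every tabulated model input (transition rates, unit costs, utilities) is one
record in a YAML parameter file.  Rates observed over a source-trial window are
converted to six-month cycle probabilities under a constant-hazard assumption.
Probabilistic-sensitivity distributions are fitted from the printed
base/lower/upper triples: Beta for probabilities (matching the central 95%
interval width), Gamma for costs and utilities (moment matching with
sd = (upper - lower)/3.92).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "DistributionSpec",
    "ProbabilityInput",
    "CostInput",
    "UtilityInput",
    "ScalarInput",
    "Settings",
    "ParameterSet",
    "LifeTable",
    "load_parameter_set",
    "rate_to_cycle_prob",
    "fit_beta_from_bounds",
    "fit_gamma_from_bounds",
]

#: scalar Table rows that map onto model settings rather than states
SCALAR_SETTING_KEYS = {
    "Age (years)": "start_age",
    "Male (%)": "male_fraction",
    "p Discount": "discount_rate_annual",
}

REQUIRED_SCALARS = ("Age (years)", "Male (%)", "p Discount")


# ---------------------------------------------------------------------------
# distributions


class DistributionSpec(BaseModel):
    """A fitted sampling distribution for one model input.

    ``point`` marks a degenerate input (zero-width bounds): sampling returns
    the base value unchanged.
    """

    model_config = ConfigDict(frozen=True)

    family: Literal["beta", "gamma", "point"]
    a: float  # alpha (beta), shape (gamma), or the point value
    b: float = 0.0  # beta (beta) or scale (gamma); unused for point

    @model_validator(mode="after")
    def _positive_params(self) -> "DistributionSpec":
        if self.family != "point" and (self.a <= 0 or self.b <= 0):
            raise ValueError(f"{self.family} parameters must be positive, got ({self.a}, {self.b})")
        return self

    def mean(self) -> float:
        if self.family == "beta":
            return self.a / (self.a + self.b)
        if self.family == "gamma":
            return self.a * self.b
        return self.a

    def sample(self, rng: np.random.Generator, size: int | tuple = ()) -> np.ndarray:
        if self.family == "beta":
            return rng.beta(self.a, self.b, size=size)
        if self.family == "gamma":
            return rng.gamma(self.a, self.b, size=size)
        return np.full(size, self.a, dtype=float)

    def interval95(self) -> tuple[float, float]:
        if self.family == "beta":
            d = stats.beta(self.a, self.b)
        elif self.family == "gamma":
            d = stats.gamma(self.a, scale=self.b)
        else:
            return (self.a, self.a)
        return (float(d.ppf(0.025)), float(d.ppf(0.975)))


def rate_to_cycle_prob(p_window, window_months, cycle_months):
    """Convert a probability observed over ``window_months`` to ``cycle_months``.

    Assumes a constant hazard within the window:
    ``p_cycle = 1 - (1 - p_window) ** (cycle_months / window_months)``.
    Accepts scalars or numpy arrays for ``p_window``.
    """
    p = np.asarray(p_window, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError(f"probability outside [0, 1]: {p_window}")
    if window_months <= 0 or cycle_months <= 0:
        raise ValueError("window_months and cycle_months must be positive")
    out = -np.expm1(np.log1p(-np.minimum(p, 1.0 - 1e-12)) * (cycle_months / window_months))
    out = np.where(p >= 1.0, 1.0, out)
    return float(out) if np.isscalar(p_window) else out


def fit_beta_from_bounds(base: float, lower: float, upper: float) -> DistributionSpec:
    """Beta distribution with mean ``base`` whose central 95% interval width
    matches ``upper - lower``.

    The mean pins alpha = base * nu, beta = (1 - base) * nu; the concentration
    nu is solved numerically.  If no nu in [1, 1e7] reproduces the width within
    1% relative, falls back to moment matching with sd = (upper - lower)/3.92
    (logged).
    """
    if not 0.0 < base < 1.0:
        raise ValueError(f"base must be in (0, 1), got {base}")
    if not lower < upper:
        raise ValueError(f"need lower < upper, got ({lower}, {upper})")
    target = upper - lower

    def width(nu: float) -> float:
        d = stats.beta(base * nu, (1.0 - base) * nu)
        return float(d.ppf(0.975) - d.ppf(0.025))

    lo, hi = 1.0, 1e7
    f_lo, f_hi = width(lo) - target, width(hi) - target
    if f_lo > 0 > f_hi:  # width decreases with nu
        nu = optimize.brentq(lambda v: width(v) - target, lo, hi, xtol=1e-9, rtol=1e-12)
        if abs(width(nu) - target) <= 0.01 * target:
            return DistributionSpec(family="beta", a=base * nu, b=(1.0 - base) * nu)
    logger.warning(
        "beta width solve failed for base=%s bounds=(%s, %s); falling back to moment matching",
        base, lower, upper,
    )
    sd = target / 3.92
    nu = base * (1.0 - base) / sd**2 - 1.0
    if nu <= 0:
        raise ValueError(f"bounds too wide for a Beta with mean {base}")
    return DistributionSpec(family="beta", a=base * nu, b=(1.0 - base) * nu)


def fit_gamma_from_bounds(base: float, lower: float, upper: float) -> DistributionSpec:
    """Gamma distribution with mean ``base`` and sd = (upper - lower)/3.92.

    Zero-width bounds yield a ``point`` spec (degenerate input).
    """
    if base <= 0:
        raise ValueError(f"base must be positive, got {base}")
    if lower < 0 or upper < 0:
        raise ValueError("bounds must be nonnegative")
    sd = (upper - lower) / 3.92
    if sd == 0.0:
        return DistributionSpec(family="point", a=base)
    if sd < 0:
        raise ValueError(f"need lower <= upper, got ({lower}, {upper})")
    shape = (base / sd) ** 2
    scale = sd**2 / base
    return DistributionSpec(family="gamma", a=shape, b=scale)


# ---------------------------------------------------------------------------
# input records


class ProbabilityInput(BaseModel):
    """One transition-rate row: a probability observed over a trial window."""

    name: str
    base: float = Field(ge=0.0, le=1.0)
    lower: float = Field(ge=0.0, le=1.0)
    upper: float = Field(ge=0.0, le=1.0)
    window_months: float = Field(default=6.0, gt=0.0)
    distribution: Literal["beta"] = "beta"
    note: Optional[str] = None

    @model_validator(mode="after")
    def _ordered_bounds(self) -> "ProbabilityInput":
        if self.lower > self.upper:
            raise ValueError(f"{self.name}: lower {self.lower} > upper {self.upper}")
        return self

    @property
    def base_outside_bounds(self) -> bool:
        return not (self.lower <= self.base <= self.upper)

    def cycle_prob(self, cycle_months: float = 6.0) -> float:
        return rate_to_cycle_prob(self.base, self.window_months, cycle_months)

    def fit(self) -> DistributionSpec:
        if self.upper == self.lower:
            return DistributionSpec(family="point", a=self.base)
        return fit_beta_from_bounds(self.base, self.lower, self.upper)


class CostInput(BaseModel):
    """One unit-cost row (CNY per unit) with a usage quantity per cycle."""

    name: str
    unit_price: float = Field(ge=0.0)
    lower: float = Field(ge=0.0)
    upper: float = Field(ge=0.0)
    units_per_cycle: float = Field(default=0.0, ge=0.0)
    category: str = "other"
    distribution: Literal["gamma"] = "gamma"
    note: Optional[str] = None

    @model_validator(mode="after")
    def _ordered(self) -> "CostInput":
        if not self.lower <= self.unit_price <= self.upper:
            raise ValueError(
                f"{self.name}: unit_price {self.unit_price} outside [{self.lower}, {self.upper}]"
            )
        return self

    def fit(self) -> DistributionSpec:
        return fit_gamma_from_bounds(self.unit_price, self.lower, self.upper)


class UtilityInput(BaseModel):
    """One utility row.  Sampled values are clamped to [0, 1] downstream."""

    name: str
    base: float = Field(ge=0.0, le=1.0)
    lower: float
    upper: float
    distribution: Literal["gamma-clamped"] = "gamma-clamped"
    note: Optional[str] = None

    @model_validator(mode="after")
    def _ordered(self) -> "UtilityInput":
        # base outside [lower, upper] is logged, not fatal (one printed row is)
        if self.lower > self.upper:
            raise ValueError(f"{self.name}: lower {self.lower} > upper {self.upper}")
        return self

    @property
    def base_outside_bounds(self) -> bool:
        return not (self.lower <= self.base <= self.upper)

    def fit(self) -> DistributionSpec:
        return fit_gamma_from_bounds(self.base, self.lower, self.upper)


class ScalarInput(BaseModel):
    """A model-level scalar (age, male fraction, discount rate) with one-way
    sensitivity bounds but no PSA distribution."""

    name: str
    base: float
    lower: float
    upper: float
    note: Optional[str] = None

    @model_validator(mode="after")
    def _ordered(self) -> "ScalarInput":
        if not self.lower <= self.base <= self.upper:
            raise ValueError(f"{self.name}: base {self.base} outside [{self.lower}, {self.upper}]")
        return self


class Settings(BaseModel):
    """Global model settings shared by every strategy."""

    start_age: float = 49.0
    male_fraction: float = Field(default=0.15, ge=0.0, le=1.0)
    discount_rate_annual: float = Field(default=0.05, ge=0.0)
    cycle_length_years: float = Field(default=0.5, gt=0.0)
    max_age: float = 100.0
    haq_floor: float = Field(default=1.5, ge=0.0)
    haq_max: float = 3.0
    mortality_haq_hr: float = Field(default=1.33, gt=0.0)
    haq_map_intercept: float
    haq_map_slope: float = Field(lt=0.0)

    @model_validator(mode="after")
    def _horizon(self) -> "Settings":
        if self.start_age >= self.max_age:
            raise ValueError("start_age must be below max_age")
        return self

    @property
    def n_cycles(self) -> int:
        return int(round((self.max_age - self.start_age) / self.cycle_length_years))


class ParameterSet(BaseModel):
    """All model inputs: tabulated rows plus global settings.

    ``reimbursement`` maps perspective name -> cost category -> fraction of the
    healthcare-system cost borne under that perspective.
    """

    schema_version: int = 1
    settings: Settings
    probabilities: list[ProbabilityInput] = Field(default_factory=list)
    costs: list[CostInput] = Field(default_factory=list)
    utilities: list[UtilityInput] = Field(default_factory=list)
    scalars: list[ScalarInput] = Field(default_factory=list)
    reimbursement: dict[str, dict[str, float]] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _unique_names(self) -> "ParameterSet":
        names = [r.name for r in (*self.probabilities, *self.costs, *self.utilities, *self.scalars)]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate parameter names: {sorted(dupes)}")
        for persp, fractions in self.reimbursement.items():
            for cat, f in fractions.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"reimbursement[{persp}][{cat}] = {f} outside [0, 1]")
        return self

    # -- lookups ------------------------------------------------------------

    def row(self, name: str):
        for group in (self.probabilities, self.costs, self.utilities, self.scalars):
            for r in group:
                if r.name == name:
                    return r
        raise KeyError(f"unknown parameter row: {name!r}")

    def probability(self, name: str) -> ProbabilityInput:
        r = self.row(name)
        if not isinstance(r, ProbabilityInput):
            raise KeyError(f"{name!r} is not a probability row")
        return r

    def cost(self, name: str) -> CostInput:
        r = self.row(name)
        if not isinstance(r, CostInput):
            raise KeyError(f"{name!r} is not a cost row")
        return r

    def utility(self, name: str) -> UtilityInput:
        r = self.row(name)
        if not isinstance(r, UtilityInput):
            raise KeyError(f"{name!r} is not a utility row")
        return r

    def base_values(self) -> dict[str, float]:
        """Base value for every row, keyed by name (rates at the window scale)."""
        vals: dict[str, float] = {}
        for r in self.probabilities:
            vals[r.name] = r.base
        for r in self.costs:
            vals[r.name] = r.unit_price
        for r in self.utilities:
            vals[r.name] = r.base
        for r in self.scalars:
            vals[r.name] = r.base
        return vals

    def effective_settings(self, overrides: Mapping[str, object] | None = None) -> Settings:
        """Settings with any scalar-row overrides (age, male fraction, discount)
        applied."""
        if not overrides:
            return self.settings
        updates = {}
        for name, key in SCALAR_SETTING_KEYS.items():
            if name in overrides:
                updates[key] = float(np.asarray(overrides[name]))
        return self.settings.model_copy(update=updates) if updates else self.settings

    def validation_report(self) -> list[str]:
        """Non-fatal data issues: rows whose base lies outside the printed bounds."""
        report = []
        for r in (*self.probabilities, *self.utilities):
            if r.base_outside_bounds:
                report.append(
                    f"{r.name}: base {r.base} outside [{r.lower}, {r.upper}]; "
                    "base kept for the deterministic case, bounds used only for dispersion"
                )
        return report

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.model_dump(exclude_none=True), sort_keys=False)
        )

    @classmethod
    def from_dict(cls, payload: dict) -> "ParameterSet":
        return cls.model_validate(payload)


def load_parameter_set(path: str | Path) -> ParameterSet:
    """Parse and validate a parameter file; non-fatal issues are logged."""
    path = Path(path)
    payload = yaml.safe_load(path.read_text())
    if not isinstance(payload, dict):
        raise ValueError(f"{path}: parameter file must be a mapping")
    params = ParameterSet.from_dict(payload)
    present = {r.name for r in params.scalars}
    for required in REQUIRED_SCALARS:
        if required not in present:
            raise KeyError(f"{path}: missing required parameter row {required!r}")
    for issue in params.validation_report():
        logger.warning("%s: %s", path.name, issue)
    return params


# ---------------------------------------------------------------------------
# life table


@dataclass(frozen=True)
class LifeTable:
    """Annual death probabilities by integer age (``qx``), 1-year steps."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        if ages.shape != qx.shape or ages.ndim != 1:
            raise ValueError("ages and qx must be matching 1-d arrays")
        if np.any(np.diff(ages) != 1):
            raise ValueError("life table must use 1-year age steps")
        if np.any((qx < 0) | (qx >= 1)):
            raise ValueError("qx must lie in [0, 1)")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def annual_qx(self, age) -> np.ndarray | float:
        """qx looked up at floor(age); fatal beyond the table range."""
        idx = np.floor(np.asarray(age, dtype=float)).astype(int) - int(self.ages[0])
        if np.any(idx < 0) or np.any(idx >= len(self.ages)):
            raise ValueError(f"age {age} outside life-table range "
                             f"[{self.ages[0]}, {self.max_age}]")
        out = self.qx[idx]
        return float(out) if np.isscalar(age) else out

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"age": self.ages, "qx": self.qx}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "LifeTable":
        df = pd.read_csv(path)
        if list(df.columns) != ["age", "qx"]:
            raise ValueError(f"{path}: life table must have columns 'age,qx'")
        return cls(ages=df["age"].to_numpy(), qx=df["qx"].to_numpy())
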