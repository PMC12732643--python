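"""Packaged fixtures: the base-case parameter file, the two treatment
pathways, payer perspectives, and scenario definitions."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from . import synthetic_data
from .markov_engine import Strategy, load_strategy
from .outcomes import Perspective, load_perspectives
from .parameters import LifeTable, ParameterSet, load_parameter_set
from .sensitivity import ScenarioSpec, load_scenario

__all__ = [
    "DEFAULT_WTP",
    "data_path",
    "default_parameters",
    "default_strategies",
    "default_combination_strategy",
    "default_perspectives",
    "default_life_table",
    "default_scenarios",
]

#: willingness-to-pay threshold: 2024 China per-capita GDP, CNY per QALY
DEFAULT_WTP = 95749.0


def data_path(name: str) -> Path:
    return Path(resources.files("ra_cea").joinpath("data", name))  # type: ignore[arg-type]


def default_parameters() -> ParameterSet:
    return load_parameter_set(data_path("parameters.yaml"))


def default_strategies() -> tuple[Strategy, Strategy]:
    """(intervention, comparator) = (rhTNFR:Fc first, MTX first)."""
    return (
        load_strategy(data_path("strategy_rhtnfr_fc.yaml")),
        load_strategy(data_path("strategy_mtx.yaml")),
    )


def default_combination_strategy() -> Strategy:
    return load_strategy(data_path("strategy_combination.yaml"))


def default_perspectives() -> dict[str, Perspective]:
    return load_perspectives(data_path("perspectives.yaml"))


def default_life_table(params: ParameterSet | None = None,
                       male_fraction: float | None = None) -> LifeTable:
    """Synthetic sex-blended life table at the cohort's male fraction."""
    if male_fraction is None:
        male_fraction = (params or default_parameters()).settings.male_fraction
    return synthetic_data.blended_life_table(male_fraction)


def default_scenarios() -> dict[str, tuple[ScenarioSpec, Strategy | None]]:
    """Named scenario fixtures: combination therapy (with +-20% treatment
    effect) and the two payer perspectives."""
    combo_spec, combo_strategy = load_scenario(data_path("scenario_combination.yaml"))
    effect_row = "p rhTNFR:Fc + MTX ACR20 response rate"
    out: dict[str, tuple[ScenarioSpec, Strategy | None]] = {
        "combination": (combo_spec, combo_strategy),
        "combination_effect_low": (
            ScenarioSpec(name="combination_effect_low",
                         overrides={effect_row: {"multiply": 0.8}}),
            combo_strategy,
        ),
        "combination_effect_high": (
            ScenarioSpec(name="combination_effect_high",
                         overrides={effect_row: {"multiply": 1.2}}),
            combo_strategy,
        ),
        "patient_oop": (ScenarioSpec(name="patient_oop", perspective="patient_oop"), None),
        "insurance": (ScenarioSpec(name="insurance", perspective="insurance"), None),
    }
    return out
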