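"""Scenario configuration: validated YAML study definitions.

A scenario is one clinical study made runnable: a population block
(demographics + disease state), a regimen block (dose and infusion
duration), a simulation block (horizon, grid, seed) and optional drug
parameter overrides.  Unknown keys are rejected so typos fail loudly
before any computation.
"""
from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .distribution import DrugParameters, cefepime_defaults
from .engine import DoseRegimen
from .physiology import PopulationDemographics

__all__ = [
    "ScenarioConfig",
    "load_scenario",
    "bundled_scenarios",
    "load_bundled_scenario",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DrugBlock(_Strict):
    """Overrides applied on top of the cefepime defaults."""

    molecular_weight: float | None = None
    log_p: float | None = None
    pka_1: float | None = None
    pka_2: float | None = None
    ionization_class: str | None = None
    fu_plasma: float | None = None
    renal_clearance_ml_min_kg: float | None = None

    def resolve(self) -> DrugParameters:
        base = cefepime_defaults()
        overrides = {k: v for k, v in self.model_dump().items() if v is not None}
        if not overrides:
            return base
        from dataclasses import replace

        return replace(base, **overrides)


class PopulationBlock(_Strict):
    n_subjects: int = Field(ge=1)
    age_range: tuple[float, float]
    weight_range: tuple[float, float]
    n_females: int = Field(default=0, ge=0)
    disease: str = "healthy"

    def resolve(self) -> PopulationDemographics:
        return PopulationDemographics(
            n_subjects=self.n_subjects,
            age_range=self.age_range,
            weight_range=self.weight_range,
            n_females=self.n_females,
            disease_state=self.disease,
        )


class RegimenBlock(_Strict):
    dose_mg: float | None = None
    dose_mg_per_kg: float | None = None
    infusion_duration_min: float = 30.0
    n_doses: int = 1
    interdose_interval_h: float = 0.0

    def resolve(self) -> DoseRegimen:
        return DoseRegimen(
            dose_mg=self.dose_mg,
            dose_mg_per_kg=self.dose_mg_per_kg,
            infusion_duration_min=self.infusion_duration_min,
            n_doses=self.n_doses,
            interdose_interval_h=self.interdose_interval_h,
        )


class SimulationBlock(_Strict):
    horizon_h: float = Field(default=12.0, gt=0)
    dt_h: float = Field(default=0.05, gt=0)
    seed: int = 0


class ScenarioConfig(_Strict):
    name: str
    description: str = ""
    population: PopulationBlock
    regimen: RegimenBlock
    simulation: SimulationBlock = SimulationBlock()
    drug: DrugBlock = DrugBlock()
    observed_data: str | None = None  # path to a two-column profile file

    @model_validator(mode="after")
    def _regimen_consistent(self) -> "ScenarioConfig":
        if (self.regimen.dose_mg is None) == (self.regimen.dose_mg_per_kg is None):
            raise ValueError("regimen must set exactly one of dose_mg / dose_mg_per_kg")
        return self


def load_scenario(path: str | Path) -> ScenarioConfig:
    """Parse and fully validate a scenario YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"scenario file {path} did not parse to a mapping")
    return ScenarioConfig.model_validate(raw)


def bundled_scenarios() -> list[str]:
    """Names of the scenario library shipped with the package."""
    root = resources.files("cefepime_pbpk").joinpath("data/scenarios")
    return sorted(p.name.removesuffix(".yaml") for p in root.iterdir() if p.name.endswith(".yaml"))


def load_bundled_scenario(name: str) -> ScenarioConfig:
    path = resources.files("cefepime_pbpk").joinpath(f"data/scenarios/{name}.yaml")
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    return ScenarioConfig.model_validate(raw)
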