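"""Run configuration: schema-validated plan, simulation and analysis blocks.

The configuration mirrors the domain types exactly (one YAML/JSON document
drives simulation, reward processing and analysis).  Validation is strict:
unknown keys are rejected before any run.
"""

from __future__ import annotations

import importlib.resources
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError as PydanticValidationError

from .protocol import PhasePlan, ProtocolError
from .simulate import BetaPrior, PopulationPriors, SimulationConfig, TruncNormalPrior
from . import io as _io

__all__ = ["RunConfig", "ConfigError", "load_config", "default_config"]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class WindowCfg(_Strict):
    scheduled_times: list[str] = ["09:00", "14:00", "20:00"]
    window_minutes: int = 30


class ScheduleCfg(_Strict):
    mode: Literal["flat", "escalating"] = "flat"
    base_amount: float = 2.00
    increment: float = 0.25
    cap: float = 3.50
    reset_outcomes: list[Literal["missed", "positive", "unverified"]] = [
        "missed",
        "positive",
        "unverified",
    ]


class PhaseCfg(_Strict):
    label: str
    condition: Literal["control", "cm"]
    duration_days: int = Field(ge=1)
    schedule: ScheduleCfg = ScheduleCfg()


class PlanCfg(_Strict):
    windows: WindowCfg = WindowCfg()
    phases: list[PhaseCfg]


class BetaPriorCfg(_Strict):
    mean: float = Field(ge=0, le=1)
    kappa: float = Field(default=40.0, gt=0)


class TruncNormalPriorCfg(_Strict):
    mean: float
    sd: float = Field(ge=0)
    low: float = 0.0
    high: float = 1.0


class PriorsCfg(_Strict):
    p_submit: dict[str, BetaPriorCfg] = {
        "A1": BetaPriorCfg(mean=0.83, kappa=40),
        "B": BetaPriorCfg(mean=0.71, kappa=40),
        "A2": BetaPriorCfg(mean=0.50, kappa=40),
    }
    p_positive: BetaPriorCfg = BetaPriorCfg(mean=0.158, kappa=60)
    cm_effect: TruncNormalPriorCfg = TruncNormalPriorCfg(mean=0.04, sd=0.02, low=0.0, high=0.5)
    p_lowquality: BetaPriorCfg = BetaPriorCfg(mean=0.06, kappa=80)
    p_impostor: BetaPriorCfg = BetaPriorCfg(mean=0.01, kappa=200)
    p_techfail: BetaPriorCfg = BetaPriorCfg(mean=0.02, kappa=100)
    p_late: float = Field(default=0.02, ge=0, le=1)


class SimulationCfg(_Strict):
    n_participants: int = Field(default=12, ge=1)
    priors: PriorsCfg = PriorsCfg()
    brac_range: tuple[float, float] = (0.01, 0.21)


class GEECfg(_Strict):
    reference_phase: str = "B"
    small_sample: bool = False


class AnalysisCfg(_Strict):
    threshold: float = Field(default=80.0, ge=0, le=100)
    denominator: Literal["scheduled", "submitted"] = "scheduled"
    count_late_as_submitted: bool = False
    control_pays_unverified: bool = True
    gee: GEECfg = GEECfg()


class RunConfig(_Strict):
    plan: PlanCfg
    simulation: SimulationCfg = SimulationCfg()
    analysis: AnalysisCfg = AnalysisCfg()
    seed: int = 0

    # ---- adapters to domain objects --------------------------------
    def phase_plan(self) -> PhasePlan:
        return _io.plan_from_dict(self.plan.model_dump())

    def population_priors(self) -> PopulationPriors:
        pr = self.simulation.priors
        return PopulationPriors(
            p_submit={
                label: BetaPrior(cfg.mean, cfg.kappa)
                for label, cfg in pr.p_submit.items()
            },
            p_positive=BetaPrior(pr.p_positive.mean, pr.p_positive.kappa),
            cm_effect=TruncNormalPrior(
                pr.cm_effect.mean, pr.cm_effect.sd, pr.cm_effect.low, pr.cm_effect.high
            ),
            p_lowquality=BetaPrior(pr.p_lowquality.mean, pr.p_lowquality.kappa),
            p_impostor=BetaPrior(pr.p_impostor.mean, pr.p_impostor.kappa),
            p_techfail=BetaPrior(pr.p_techfail.mean, pr.p_techfail.kappa),
            p_late=pr.p_late,
        )

    def simulation_config(self, seed: int | None = None) -> SimulationConfig:
        return SimulationConfig(
            n_participants=self.simulation.n_participants,
            plan=self.phase_plan(),
            seed=self.seed if seed is None else seed,
            priors=self.population_priors(),
            brac_range=tuple(self.simulation.brac_range),
        )


def _validate(payload: dict) -> RunConfig:
    try:
        return RunConfig.model_validate(payload)
    except PydanticValidationError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str) -> tuple[RunConfig, str]:
    """Load and validate a YAML/JSON config; returns (config, raw text)."""
    try:
        payload, text = _io.load_config_text(path)
    except (OSError, yaml.YAMLError, ValueError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(payload, dict):
        raise ConfigError("config root must be a mapping")
    return _validate(payload), text


def default_config() -> tuple[RunConfig, str]:
    """The packaged default configuration (the 14/28/14 A-B-A study plan)."""
    text = (
        importlib.resources.files("remotecm").joinpath("data/default_config.yaml")
    ).read_text()
    return _validate(yaml.safe_load(text)), text
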