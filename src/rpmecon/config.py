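"""Run configuration: YAML loading, validation, round-tripping.

A config file is a flat YAML mapping. Keys mirroring ``ClinicParameters``
field names override the packaged defaults (the published reference
values); the remaining keys control scenario selection, the sensitivity
grid, the demand simulation, and output. Unknown keys are rejected rather
than ignored, so typos surface immediately.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from importlib import resources
from pathlib import Path

import yaml

from .clinic_model import ClinicParameters
from .sensitivity import PERTURBABLE, SCENARIOS

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config",
           "default_config_path"]


class ConfigError(ValueError):
    """A config file failed to parse or validate."""


_CLINIC_FIELDS = {f.name for f in fields(ClinicParameters)}


@dataclass(frozen=True)
class RunConfig:
    """Validated settings for one model run."""

    clinic: ClinicParameters = field(default_factory=ClinicParameters)
    scenario: str = "capacity-neutral"
    sensitivity_parameters: tuple[str, ...] = ("routine_rate",
                                               "routine_minutes",
                                               "cdces_salary",
                                               "cdces_capacity")
    sensitivity_multipliers: tuple[float, ...] = (1.5, 0.5)
    simulation_model: str = "bernoulli"
    simulation_seed: int = 0
    simulation_replicates: int = 1
    output_dir: str = "rpmecon-output"
    output_formats: tuple[str, ...] = ("csv", "md")

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigError(f"scenario must be one of {SCENARIOS}")
        bad = set(self.sensitivity_parameters) - set(PERTURBABLE)
        if bad:
            raise ConfigError(f"unknown sensitivity parameters: {sorted(bad)}")
        if any(m <= 0 for m in self.sensitivity_multipliers):
            raise ConfigError("sensitivity multipliers must be > 0")
        if self.simulation_model not in ("bernoulli", "cgm-metric"):
            raise ConfigError("simulation_model must be bernoulli|cgm-metric")
        if self.simulation_replicates < 1:
            raise ConfigError("simulation_replicates must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        clinic = d.pop("clinic")
        clinic["coverage_by_year"] = list(clinic["coverage_by_year"])
        d["sensitivity_parameters"] = list(self.sensitivity_parameters)
        d["sensitivity_multipliers"] = list(self.sensitivity_multipliers)
        d["output_formats"] = list(self.output_formats)
        return {**clinic, **d}


def default_config_path() -> Path:
    """Path of the packaged default config (the reference parameter set)."""
    return Path(resources.files("rpmecon") / "data" / "defaults.yaml")


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config; omitted keys take the defaults."""
    raw = {}
    if path is not None:
        try:
            text = Path(path).read_text()
            raw = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"could not parse {path}: {exc}") from exc
        if not isinstance(raw, dict):
            raise ConfigError(f"{path} must contain a key: value mapping")

    run_fields = {f.name for f in fields(RunConfig)} - {"clinic"}
    clinic_kwargs, run_kwargs = {}, {}
    for key, value in raw.items():
        if key in _CLINIC_FIELDS:
            clinic_kwargs[key] = value
        elif key in run_fields:
            if key in ("sensitivity_parameters", "sensitivity_multipliers",
                       "output_formats"):
                value = tuple(value)
            run_kwargs[key] = value
        else:
            raise ConfigError(f"unknown config key: {key!r}")
    try:
        clinic = ClinicParameters(**clinic_kwargs)
        return RunConfig(clinic=clinic, **run_kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config as flat YAML; ``load_config`` restores it exactly."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
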