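"""Run configuration: a single YAML/JSON file describing every parameter.

The file mirrors the package's parameter objects as nested sections
(``scale``, ``field``, ``model``, ``exposure``, ``decay_i``, ``decay_j``,
``grid``, ``strategy``) plus an output directory and a seed.  Every key is
optional — an empty file yields the standard defaults — but unknown keys are
rejected with an error naming the offending key, and every constraint
violation names the key and the constraint.
"""

import dataclasses
import hashlib
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import yaml

from .decay import DecayProfile, InsecticideSpec
from .grids import GridSpec
from .mapping import FieldSurvivalParams, ResistanceScale
from .selection import ExposureConfig, ModelParams
from .strategy import StrategyConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config", "config_hash"]


class ConfigError(ValueError):
    """A configuration file failed to parse or validate."""


@dataclass(frozen=True)
class ModelSection:
    """Genetic parameters (scalar part of :class:`ModelParams`)."""

    h2_i: float = 0.2
    h2_j: float = 0.2
    cross_resistance: float = 0.0
    exposure_scaling: float = 1.0
    cost_differential_i_female: float = 0.0
    cost_differential_i_male: float = 0.0
    cost_differential_j_female: float = 0.0
    cost_differential_j_male: float = 0.0
    survival_floor: float = 1e-10


@dataclass(frozen=True)
class GridSection:
    """Sweep ranges for the single-generation grids."""

    efficacy_values: Sequence[float] = GridSpec.efficacy_values
    exposure_values: Sequence[float] = GridSpec.exposure_values
    resistance_levels: Sequence[float] = GridSpec.resistance_levels
    heritability: float = 0.2
    sigma: float = 20.0
    exposure_scaling: float = 1.0


@dataclass(frozen=True)
class StrategySection:
    """Multi-generation strategy settings."""

    strategy: Literal["sequence", "mixture"] = "sequence"
    withdrawal_threshold: float = 10.0
    return_threshold: float = 8.0
    deployment_frequency: int = 30
    max_generations: int = 500
    generations_per_year: int = 10
    initial_mean_i: float = 0.0
    initial_mean_j: float = 0.0
    sigma: float = 20.0
    monitor: Literal["treated", "global"] = "treated"
    deployment_order: tuple = ("i", "j")
    mixture_deployed_efficacy: float = 1.0

    def __post_init__(self) -> None:
        if not self.return_threshold < self.withdrawal_threshold:
            raise ValueError(
                "return_threshold must be below withdrawal_threshold "
                f"(got {self.return_threshold} >= {self.withdrawal_threshold})"
            )


@dataclass(frozen=True)
class RunConfig:
    """Fully validated configuration with defaults filled in."""

    scale: ResistanceScale = dc_field(default_factory=ResistanceScale)
    field: FieldSurvivalParams = dc_field(default_factory=FieldSurvivalParams)
    model: ModelSection = dc_field(default_factory=ModelSection)
    exposure: ExposureConfig = dc_field(default_factory=ExposureConfig)
    decay_i: DecayProfile = dc_field(default_factory=DecayProfile)
    decay_j: DecayProfile = dc_field(default_factory=DecayProfile)
    grid: GridSection = dc_field(default_factory=GridSection)
    strategy: StrategySection = dc_field(default_factory=StrategySection)
    output_dir: str = "results"
    seed: int = 0

    # -- wiring into the model objects -------------------------------------

    def model_params(self) -> ModelParams:
        return ModelParams(
            **dataclasses.asdict(self.model),
            field_params=self.field,
            scale=self.scale,
        )

    def grid_spec(self, mode: str = "monotherapy") -> GridSpec:
        return GridSpec(
            **dataclasses.asdict(self.grid),
            mode=mode,
            scale=self.scale,
            field_params=self.field,
        )

    def strategy_config(
        self, strategy: Optional[str] = None, record_trajectory: bool = True
    ) -> StrategyConfig:
        s = self.strategy
        return StrategyConfig(
            strategy=strategy or s.strategy,
            coverage=self.exposure.coverage,
            dispersal=self.exposure.dispersal,
            female_exposure=self.exposure.female_exposure,
            male_ratio=self.exposure.male_ratio,
            withdrawal_threshold=s.withdrawal_threshold,
            return_threshold=s.return_threshold,
            deployment_frequency=s.deployment_frequency,
            max_generations=s.max_generations,
            generations_per_year=s.generations_per_year,
            insecticide_i=InsecticideSpec("i", self.decay_i),
            insecticide_j=InsecticideSpec("j", self.decay_j),
            model_params=self.model_params(),
            initial_mean_i=s.initial_mean_i,
            initial_mean_j=s.initial_mean_j,
            sigma=s.sigma,
            monitor=s.monitor,
            deployment_order=tuple(s.deployment_order),
            record_trajectory=record_trajectory,
        )


def _build(cls, data, path: str):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    for key in data:
        if key not in fields:
            raise ConfigError(f"unknown key {path}.{key}" if path else f"unknown key {key}")
    kwargs = {}
    for name, f in fields.items():
        if name not in data:
            continue
        value = data[name]
        sub = f"{path}.{name}" if path else name
        if dataclasses.is_dataclass(f.type):
            value = _build(f.type, value, sub)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{path or cls.__name__}: {exc}") from exc


def load_config(path: Union[str, Path, None] = None) -> RunConfig:
    """Load and validate a YAML (or JSON) configuration file.

    ``None`` or an empty file yields all defaults.
    """
    data = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"could not parse {path}: {exc}") from exc
        if data is None:
            data = {}
    return _build(RunConfig, data, "")


def _plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_plain(v) for v in obj]
    return obj


def save_config(config: RunConfig, path: Union[str, Path]) -> None:
    """Write a configuration back to YAML; load(save(c)) == c."""
    Path(path).write_text(yaml.safe_dump(_plain(config), sort_keys=False))


def config_hash(config: RunConfig) -> str:
    """Short stable digest of the full configuration."""
    canonical = yaml.safe_dump(_plain(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
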