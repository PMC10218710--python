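"""Run configuration: defaults, YAML/JSON loading, validation."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dosimetry import DriveSignal, SolenoidSpec, TissueParams
from .synthetic_rt import GeneratorParams


class ConfigError(ValueError):
    """Invalid run configuration; the message names the failing field."""


@dataclass(frozen=True)
class SchedulerConfig:
    block_order: tuple[int, ...] = (1, 2, 3, 4)
    trials_per_block: int = 12
    target_fraction: float = 0.5
    max_run: int = 3
    max_attempts: int = 10_000
    n_target_pool: int = 9
    n_foil_pool: int = 12

    def __post_init__(self) -> None:
        if self.trials_per_block < 1:
            raise ConfigError("scheduler.trials_per_block must be >= 1")
        if not 0.0 <= self.target_fraction <= 1.0:
            raise ConfigError("scheduler.target_fraction must be in [0, 1]")
        if self.max_run < 1:
            raise ConfigError("scheduler.max_run must be >= 1")


@dataclass(frozen=True)
class GridConfig:
    x_mm: tuple[float, float, float] = (-30.0, 30.0, 10.0)
    y_mm: tuple[float, float, float] = (-30.0, 30.0, 10.0)
    z_mm: tuple[float, float, float] = (0.0, 140.0, 10.0)


@dataclass(frozen=True)
class DosimetryConfig:
    solenoid: SolenoidSpec = field(default_factory=SolenoidSpec)
    drive: DriveSignal = field(default_factory=DriveSignal)
    tissue: TissueParams = field(default_factory=TissueParams)
    grid: GridConfig = field(default_factory=GridConfig)
    head_width_m: float = 0.14
    coils_per_side: int = 2
    segments_per_turn: int = 16

    def __post_init__(self) -> None:
        if self.coils_per_side < 1:
            raise ConfigError("dosimetry.coils_per_side must be >= 1")
        if self.segments_per_turn < 3:
            raise ConfigError("dosimetry.segments_per_turn must be >= 3")


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    n_exposed: int = 34
    n_sham: int = 31
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    scheduler: SchedulerConfig = field(default_factory=SchedulerConfig)
    dosimetry: DosimetryConfig = field(default_factory=DosimetryConfig)

    def __post_init__(self) -> None:
        if self.n_exposed < 0 or self.n_sham < 0:
            raise ConfigError("cohort sizes n_exposed / n_sham must be non-negative")
        if self.n_exposed + self.n_sham < 2:
            raise ConfigError("cohort must have at least two subjects")


def _build(cls, data: dict, path: str):
    """Construct a (nested) dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError(f"{path or 'config'} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown field(s) {sorted(unknown)} in {path or 'config'}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        sub = {
            "GeneratorParams": GeneratorParams,
            "SchedulerConfig": SchedulerConfig,
            "DosimetryConfig": DosimetryConfig,
            "SolenoidSpec": SolenoidSpec,
            "DriveSignal": DriveSignal,
            "TissueParams": TissueParams,
            "GridConfig": GridConfig,
        }.get(str(ftype).split(".")[-1].strip("'\" "))
        if sub is not None and isinstance(value, dict):
            kwargs[name] = _build(sub, value, f"{path}.{name}" if path else name)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in {path or 'config'}: {exc}") from exc


def config_from_dict(data: dict) -> RunConfig:
    return _build(RunConfig, data or {}, "")


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file (None = all defaults)."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return config_from_dict(data or {})


def config_to_dict(config) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: convert(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, tuple):
            return [convert(x) for x in obj]
        return obj

    return convert(config)


def config_hash(config: RunConfig) -> str:
    """Stable SHA-256 of the canonical JSON form of the configuration."""
    canon = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()
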