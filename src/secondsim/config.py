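"""Structured run configuration (YAML) with strict schema validation.

A run configuration names a shipped dyad preset (or spells out agent and
strategy parameters inline), the session/batch settings and the validation
settings.  Unknown keys are rejected so typos fail loudly, and the
write -> read -> write round trip is idempotent.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .core import AgentParams
from .simulate import DEFAULT_N_STEPS, DEFAULT_STEP_SECONDS, SessionConfig
from .strategies import (
    DyadPreset,
    EmotionPolicy,
    PRESET_NAMES,
    StrategyParams,
    dyad_preset,
)
from .validation import DEFAULT_GRID_SIZE, DENSITY_FLOOR

__all__ = ["RunConfig", "load_config", "dump_config", "dyad_from_config"]


@dataclass(frozen=True, slots=True)
class ValidationSettings:
    grid_size: int = DEFAULT_GRID_SIZE
    floor: float = DENSITY_FLOOR
    bandwidth: str | float = "silverman"
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if self.grid_size < 8:
            raise ValueError("grid_size must be >= 8")
        if self.floor <= 0:
            raise ValueError("floor must be > 0")


@dataclass(frozen=True, slots=True)
class RunConfig:
    """Everything needed to reproduce a simulation + validation run."""

    preset: str | None = "play_centered"
    child: dict | None = None
    parent: dict | None = None
    parent_strategy: dict | None = None
    n_steps: int = DEFAULT_N_STEPS
    step_seconds: float = DEFAULT_STEP_SECONDS
    n_sessions: int = 2000
    seed: int = 0
    validation: ValidationSettings = field(default_factory=ValidationSettings)

    def __post_init__(self) -> None:
        inline = self.child is not None or self.parent is not None
        if self.preset is None and not inline:
            raise ValueError("either a preset name or inline parameters required")
        if self.preset is not None and inline:
            raise ValueError("give a preset name or inline parameters, not both")
        if self.preset is not None and self.preset not in PRESET_NAMES:
            raise ValueError(
                f"unknown preset {self.preset!r}; valid: {', '.join(PRESET_NAMES)}"
            )
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be >= 1")


def _from_mapping(cls, data: dict, where: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) in {where}: {', '.join(sorted(unknown))}"
        )
    return cls(**data)


def _strategy_from_mapping(data: dict) -> StrategyParams:
    data = dict(data)
    policy = data.pop("emotion_policy", None)
    for key in ("scaffold_band", "symmetry_conditional", "satiation_bias"):
        if data.get(key) is not None:
            data[key] = tuple(data[key])
    strategy = _from_mapping(StrategyParams, data, "parent_strategy")
    if policy is not None:
        policy = _from_mapping(EmotionPolicy, policy, "emotion_policy")
        strategy = StrategyParams(
            **{
                **{f.name: getattr(strategy, f.name) for f in fields(StrategyParams)},
                "emotion_policy": policy,
            }
        )
    return strategy


def dyad_from_config(config: RunConfig) -> DyadPreset:
    """Materialize the dyad named or described by a configuration."""
    if config.preset is not None:
        return dyad_preset(config.preset)
    if config.child is None or config.parent is None:
        raise ValueError("inline configuration needs both child and parent")
    return DyadPreset(
        child=_from_mapping(AgentParams, config.child, "child"),
        parent=_from_mapping(AgentParams, config.parent, "parent"),
        parent_strategy=_strategy_from_mapping(config.parent_strategy or {}),
        label="custom",
    )


def session_config(config: RunConfig) -> SessionConfig:
    return SessionConfig(
        dyad=dyad_from_config(config),
        n_steps=config.n_steps,
        step_seconds=config.step_seconds,
        seed=config.seed,
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    data = dict(data)
    validation = data.pop("validation", None)
    config = _from_mapping(RunConfig, data, "run config")
    if validation is not None:
        validation = _from_mapping(ValidationSettings, validation, "validation")
        config = RunConfig(
            **{
                **{
                    f.name: getattr(config, f.name)
                    for f in fields(RunConfig)
                    if f.name != "validation"
                },
                "validation": validation,
            }
        )
    return config


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration back to YAML."""
    data = asdict(config)
    if config.preset is not None:
        for key in ("child", "parent", "parent_strategy"):
            data.pop(key, None)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))
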