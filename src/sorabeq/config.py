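"""Configuration schema and YAML loader.

One key-value file shared by every command, with four sections
(``structural``, ``variability``, ``design``, ``engine``).  Missing keys
fall back to the shipped defaults (the published population point
estimates and the study design); unknown keys are rejected, and every
violation in a file is reported at once.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .params import ParameterError, StructuralParams, VariabilityParams

__all__ = ["ConfigError", "DesignConfig", "EngineConfig", "RunConfig",
           "load_config", "dump_config"]


class ConfigError(ValueError):
    """Invalid configuration; the message lists every violation."""


@dataclass(frozen=True)
class DesignConfig:
    kind: str = "crossover_2x2"      # or replicated_two_period
    n_subjects: int = 36
    dose_test: float = 125.0
    dose_ref: float = 200.0


@dataclass(frozen=True)
class EngineConfig:
    n_trials: int = 500
    seed: int = 12345
    rtol: float = 1e-7
    atol: float = 1e-9
    censor_lloq: bool = False
    lloq: float = 5.0


@dataclass(frozen=True)
class RunConfig:
    structural: StructuralParams
    variability: VariabilityParams
    design: DesignConfig
    engine: EngineConfig


_SECTIONS = {
    "structural": StructuralParams,
    "variability": VariabilityParams,
    "design": DesignConfig,
    "engine": EngineConfig,
}


def _build_section(name, cls, mapping, problems):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        problems.append(f"{name}: unknown keys {sorted(unknown)}")
        mapping = {k: v for k, v in mapping.items() if k in known}
    try:
        return cls(**mapping)
    except (ParameterError, TypeError, ValueError) as exc:
        problems.append(f"{name}: {exc}")
        return cls()


def load_config(path: str | None = None) -> RunConfig:
    """Load a config file merged over the shipped defaults.

    ``path=None`` returns the pure defaults.
    """
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config root must be a mapping, got "
                              f"{type(raw).__name__}")
    problems: list[str] = []
    unknown_sections = set(raw) - set(_SECTIONS)
    if unknown_sections:
        problems.append(f"unknown sections {sorted(unknown_sections)}")
    built = {name: _build_section(name, cls, raw.get(name, {}) or {}, problems)
             for name, cls in _SECTIONS.items()}
    if problems:
        raise ConfigError("; ".join(problems))
    return RunConfig(**built)


def dump_config(cfg: RunConfig, path: str) -> None:
    """Write a config back to YAML (round-trips with load_config)."""
    data = {name: asdict(getattr(cfg, name)) for name in _SECTIONS}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
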