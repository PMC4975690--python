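"""Run-configuration loading, validation and serialization (YAML dialect).

A run configuration has sections ``model``, ``env`` and ``ibm`` mapping onto
the parameter dataclasses, plus run-level keys (engine, variant, generations,
seed, output path).  A ``preset`` key seeds every section with a named
preset's frozen parameters before explicit keys override them.  Unknown keys
are hard errors: silent typos are the main failure mode for parameter-heavy
models.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError, ParameterError
from .params import EnvParams, IBMParams, ModelParams
from .scenarios import VARIANTS, get_preset

SCHEMA_VERSION = 1

_RUN_KEYS = {"schema_version", "preset", "engine", "variant", "n_generations",
             "seed", "out", "format", "log_level", "model", "env", "ibm"}

log = logging.getLogger("matevolve")


@dataclass
class RunConfig:
    """Fully validated run configuration."""

    model: ModelParams = field(default_factory=ModelParams)
    env: EnvParams = field(default_factory=EnvParams)
    ibm: IBMParams = field(default_factory=IBMParams)
    engine: str = "analytic"
    variant: str = "both"
    n_generations: int = 50_000
    seed: int = 0
    out: str | None = None
    format: str = "tsv"
    log_level: str = "INFO"
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.engine not in ("analytic", "ibm", "both"):
            raise ConfigError(f"engine must be analytic|ibm|both, "
                              f"got {self.engine!r}")
        if self.variant not in VARIANTS:
            raise ConfigError(f"variant must be one of {VARIANTS}")
        if self.schema_version != SCHEMA_VERSION:
            raise ConfigError(
                f"unsupported schema_version {self.schema_version} "
                f"(expected {SCHEMA_VERSION})")
        if self.n_generations < 1:
            raise ConfigError("n_generations must be >= 1")
        if self.env.scenario == "two_patch" and self.engine != "ibm":
            raise ConfigError("the two_patch scenario requires engine: ibm")

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "engine": self.engine,
            "variant": self.variant,
            "n_generations": self.n_generations,
            "seed": self.seed,
            "out": self.out,
            "format": self.format,
            "log_level": self.log_level,
            "model": dataclasses.asdict(self.model),
            "env": dataclasses.asdict(self.env),
            "ibm": dataclasses.asdict(self.ibm),
        }


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section {section!r}; "
            f"valid keys: {sorted(valid)}")
    try:
        return cls(**data)
    except ParameterError as exc:
        raise ConfigError(f"section {section!r}: {exc}") from exc


def config_from_dict(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(raw) - _RUN_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}; "
                          f"valid keys: {sorted(_RUN_KEYS)}")
    raw = dict(raw)
    preset_name = raw.pop("preset", None)
    sections = {"model": {}, "env": {}, "ibm": {}}
    defaults: dict = {}
    if preset_name is not None:
        preset = get_preset(preset_name)
        sections["model"] = dataclasses.asdict(preset.model)
        sections["env"] = dataclasses.asdict(preset.env)
        sections["ibm"] = dataclasses.asdict(preset.ibm)
        defaults["engine"] = preset.engines[0]
        defaults["n_generations"] = preset.n_generations
    for name in ("model", "env", "ibm"):
        override = raw.pop(name, {}) or {}
        if not isinstance(override, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        sections[name].update(override)
    model = _build_section(ModelParams, sections["model"], "model")
    env = _build_section(EnvParams, sections["env"], "env")
    ibm = _build_section(IBMParams, sections["ibm"], "ibm")
    kwargs = {**defaults, **raw}
    try:
        return RunConfig(model=model, env=env, ibm=ibm, **kwargs)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path) -> RunConfig:
    """Load and fully validate a YAML run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def save_config(config: RunConfig, path) -> Path:
    """Serialize a RunConfig; ``load_config`` of the result round-trips."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return path


def log_run_header(config: RunConfig) -> None:
    """Log the fully resolved parameter set and seed for reproducibility."""
    log.info("resolved run configuration: %s", config.to_dict())
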