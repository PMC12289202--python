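"""Run configuration: YAML loading, validation and defaults.

A run configuration is a single YAML file with a ``params`` block (model
constants, defaulting to the baseline values) and optional per-command
blocks (``basins``, ``bifurcation``, ``hysteresis``, ``ibm``).  Unspecified
fields take the documented defaults, so an empty file is a valid, fully
default configuration.  Configurations round-trip losslessly through
``save_config``/``load_config``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .ibm import IBMConfig
from .model import ModelParams

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    """Raised with a field-by-field list of schema violations."""


@dataclass
class RunConfig:
    """Validated run configuration with baseline defaults."""

    params: ModelParams = field(default_factory=ModelParams)
    basins: dict[str, Any] = field(default_factory=dict)
    bifurcation: dict[str, Any] = field(default_factory=dict)
    hysteresis: dict[str, Any] = field(default_factory=dict)
    ibm: dict[str, Any] = field(default_factory=dict)
    output_dir: str = "."
    seed: int = 0
    verbosity: str = "INFO"

    def ibm_config(self) -> IBMConfig:
        kwargs = dict(self.ibm)
        kwargs.setdefault("seed", self.seed)
        return IBMConfig(params=self.params, **kwargs)

    def to_dict(self) -> dict:
        return {
            "params": dataclasses.asdict(self.params),
            "basins": dict(self.basins),
            "bifurcation": dict(self.bifurcation),
            "hysteresis": dict(self.hysteresis),
            "ibm": dict(self.ibm),
            "output_dir": self.output_dir,
            "seed": self.seed,
            "verbosity": self.verbosity,
        }


_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}
_TOP_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}
_SECTION_FIELDS = {"basins", "bifurcation", "hysteresis", "ibm"}


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    ``path=None`` (or an empty file) yields full defaults.  All schema
    violations are collected and reported together, naming each offending
    field.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        raw = loaded

    errors: list[str] = []
    for key in raw:
        if key not in _TOP_FIELDS:
            errors.append(f"unknown top-level field {key!r}")

    params_raw = raw.get("params", {}) or {}
    params_errors: list[str] = []
    if not isinstance(params_raw, dict):
        params_errors.append("params: must be a mapping")
        params_raw = {}
    for key, value in params_raw.items():
        if key not in _PARAM_FIELDS:
            params_errors.append(f"params.{key}: unknown parameter")
        elif not isinstance(value, (int, float)) or isinstance(value, bool):
            params_errors.append(f"params.{key}: must be a number, got {value!r}")

    params = None
    if not params_errors:
        try:
            params = ModelParams(**params_raw)
        except ValueError as exc:
            params_errors.append(f"params: {exc}")
    errors.extend(params_errors)

    sections: dict[str, dict] = {}
    for name in _SECTION_FIELDS:
        block = raw.get(name, {}) or {}
        if not isinstance(block, dict):
            errors.append(f"{name}: must be a mapping")
            block = {}
        sections[name] = block

    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool):
        errors.append(f"seed: must be an integer, got {seed!r}")
        seed = 0
    output_dir = raw.get("output_dir", ".")
    if not isinstance(output_dir, str):
        errors.append(f"output_dir: must be a string, got {output_dir!r}")
        output_dir = "."
    verbosity = raw.get("verbosity", "INFO")
    if verbosity not in ("DEBUG", "INFO", "WARNING", "ERROR"):
        errors.append(f"verbosity: must be a logging level name, got {verbosity!r}")
        verbosity = "INFO"

    if errors:
        raise ConfigError(
            "invalid configuration:\n  " + "\n  ".join(errors)
        )
    assert params is not None
    return RunConfig(
        params=params,
        basins=sections["basins"],
        bifurcation=sections["bifurcation"],
        hysteresis=sections["hysteresis"],
        ibm=sections["ibm"],
        output_dir=output_dir,
        seed=seed,
        verbosity=verbosity,
    )


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a configuration to YAML (inverse of ``load_config``)."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
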