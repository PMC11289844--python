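"""Configuration loading for runs of the settlement-game analysis.

A run config is a flat YAML (or JSON) document::

    parameters: baseline        # or a mapping with the ten canonical keys
    overrides: {u2: 7}          # optional per-parameter overrides
    seed: 0
    log_level: INFO
    integration: {t_max: 500}   # optional IntegrationSettings overrides
    grid: {step: 0.1, include_boundary: false}
    sweep: {parameter: u1, values: [1, 2, 3]}
    output: {directory: out, plots: false}

Unknown keys at any level are errors, as are missing or non-numeric
parameter values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from numbers import Real
from pathlib import Path
from typing import Any, Mapping

import yaml

from .dynamics import IntegrationSettings
from .model import GameParameters, PARAM_NAMES, baseline_parameters

__all__ = ["ConfigError", "RunConfig", "load_config", "parse_config"]

_TOP_KEYS = {
    "parameters", "overrides", "seed", "log_level",
    "integration", "grid", "sweep", "output",
}
_GRID_KEYS = {"step", "include_boundary"}
_SWEEP_KEYS = {"parameter", "values"}
_OUTPUT_KEYS = {"directory", "plots"}


class ConfigError(ValueError):
    """Malformed run configuration; the message names the offending key."""


@dataclass(frozen=True)
class RunConfig:
    """A fully validated run configuration with defaults filled in."""

    parameters: GameParameters
    seed: int = 0
    log_level: str = "INFO"
    integration: IntegrationSettings = field(default_factory=IntegrationSettings)
    grid_step: float = 0.1
    grid_include_boundary: bool = False
    sweep_parameter: str | None = None
    sweep_values: tuple[float, ...] = ()
    output_directory: Path | None = None
    plots: bool = False


def _require_number(value: Any, key: str) -> float:
    if isinstance(value, bool) or not isinstance(value, Real):
        raise ConfigError(f"value for {key!r} must be a number, got {value!r}")
    return float(value)


def _parse_parameters(block: Any, overrides: Any) -> GameParameters:
    if block == "baseline":
        params = baseline_parameters()
    elif isinstance(block, Mapping):
        unknown = set(block) - set(PARAM_NAMES)
        if unknown:
            raise ConfigError(f"unknown parameter keys: {sorted(unknown)}")
        missing = set(PARAM_NAMES) - set(block)
        if missing:
            raise ConfigError(f"missing parameter keys: {sorted(missing)}")
        params = GameParameters(
            **{k: _require_number(block[k], f"parameters.{k}") for k in PARAM_NAMES}
        )
    else:
        raise ConfigError(
            "parameters must be the literal 'baseline' or a mapping of the "
            f"ten keys {PARAM_NAMES}"
        )
    if overrides is not None:
        if not isinstance(overrides, Mapping):
            raise ConfigError("overrides must be a mapping")
        unknown = set(overrides) - set(PARAM_NAMES)
        if unknown:
            raise ConfigError(f"unknown override keys: {sorted(unknown)}")
        params = params.replace(
            **{k: _require_number(v, f"overrides.{k}") for k, v in overrides.items()}
        )
    return params


def parse_config(doc: Mapping[str, Any]) -> RunConfig:
    """Validate a parsed configuration mapping into a :class:`RunConfig`."""
    if not isinstance(doc, Mapping):
        raise ConfigError("configuration root must be a mapping")
    unknown = set(doc) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
    if "parameters" not in doc:
        raise ConfigError("missing required key 'parameters'")
    params = _parse_parameters(doc["parameters"], doc.get("overrides"))

    seed = doc.get("seed", 0)
    if isinstance(seed, bool) or not isinstance(seed, int) or seed < 0:
        raise ConfigError(f"seed must be a nonnegative integer, got {seed!r}")

    log_level = doc.get("log_level", "INFO")
    if not isinstance(log_level, str):
        raise ConfigError("log_level must be a string")

    integration_block = doc.get("integration", {})
    if not isinstance(integration_block, Mapping):
        raise ConfigError("integration must be a mapping")
    valid = {f.name for f in dataclasses.fields(IntegrationSettings)}
    unknown = set(integration_block) - valid
    if unknown:
        raise ConfigError(f"unknown integration keys: {sorted(unknown)}")
    try:
        integration = IntegrationSettings(
            **{
                k: _require_number(v, f"integration.{k}")
                for k, v in integration_block.items()
            }
        )
    except ValueError as exc:
        raise ConfigError(f"invalid integration settings: {exc}") from exc

    grid_block = doc.get("grid", {})
    if not isinstance(grid_block, Mapping):
        raise ConfigError("grid must be a mapping")
    unknown = set(grid_block) - _GRID_KEYS
    if unknown:
        raise ConfigError(f"unknown grid keys: {sorted(unknown)}")
    grid_step = _require_number(grid_block.get("step", 0.1), "grid.step")
    include_boundary = bool(grid_block.get("include_boundary", False))

    sweep_block = doc.get("sweep")
    sweep_parameter: str | None = None
    sweep_values: tuple[float, ...] = ()
    if sweep_block is not None:
        if not isinstance(sweep_block, Mapping):
            raise ConfigError("sweep must be a mapping")
        unknown = set(sweep_block) - _SWEEP_KEYS
        if unknown:
            raise ConfigError(f"unknown sweep keys: {sorted(unknown)}")
        sweep_parameter = sweep_block.get("parameter")
        if sweep_parameter not in PARAM_NAMES:
            raise ConfigError(f"sweep.parameter must be one of {PARAM_NAMES}")
        raw_values = sweep_block.get("values")
        if not isinstance(raw_values, (list, tuple)) or not raw_values:
            raise ConfigError("sweep.values must be a non-empty list of numbers")
        sweep_values = tuple(
            _require_number(v, "sweep.values") for v in raw_values
        )

    output_block = doc.get("output", {})
    if not isinstance(output_block, Mapping):
        raise ConfigError("output must be a mapping")
    unknown = set(output_block) - _OUTPUT_KEYS
    if unknown:
        raise ConfigError(f"unknown output keys: {sorted(unknown)}")
    directory = output_block.get("directory")
    output_directory = Path(directory) if directory is not None else None

    return RunConfig(
        parameters=params,
        seed=seed,
        log_level=log_level,
        integration=integration,
        grid_step=grid_step,
        grid_include_boundary=include_boundary,
        sweep_parameter=sweep_parameter,
        sweep_values=sweep_values,
        output_directory=output_directory,
        plots=bool(output_block.get("plots", False)),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration from ``path``."""
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config file {path}: {exc}") from exc
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
    if doc is None:
        raise ConfigError(f"config file {path} is empty")
    return parse_config(doc)
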