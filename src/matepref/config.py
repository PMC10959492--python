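"""YAML configuration for model runs.

Schema (all sections optional; defaults are the model's printed defaults)::

    params:                # ModelParams fields
      s1: 0.02
      cri: 0.0025
    run:
      gamma_t0: 0.5        # ancestral weighting
      gamma_r: 0.5         # resident weighting for single-point commands
    gradient:              # GradientSettings fields
      delta_gamma: 1.0e-3
    sweep:                 # see matepref.sweeps.SweepSpec
      axis1: {name: s1, values: [0.005, 0.01, 0.02]}
      axis2: {name: cri, values: [0.0, 0.0025, 0.005]}
      gamma_t0: [0.5]
      fixed: {s2: 0.0}
      output: sweep.tsv

Unknown keys and out-of-range values raise a validation error naming the
offending field.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

from .invasion import GradientSettings
from .params import ModelParams, default_params

_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}
_GRADIENT_FIELDS = {f.name for f in dataclasses.fields(GradientSettings)}
_RUN_FIELDS = {"gamma_t0", "gamma_r"}
_TOP_LEVEL = {"params", "run", "gradient", "sweep"}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Parsed configuration: parameters plus run/solver settings."""

    params: ModelParams
    gamma_t0: float = 0.5
    gamma_r: float = 0.5
    gradient: GradientSettings = dataclasses.field(default_factory=GradientSettings)
    sweep: dict[str, Any] | None = None


def _check_keys(section: str, data: dict, allowed: set[str]) -> None:
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) in '{section}': {sorted(unknown)}; "
                         f"allowed: {sorted(allowed)}")


def build_params(overrides: dict[str, Any] | None = None) -> ModelParams:
    """Default parameters with validated field overrides."""
    overrides = overrides or {}
    _check_keys("params", overrides, _PARAM_FIELDS)
    return ModelParams(**overrides)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML config file."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    _check_keys("config", raw, _TOP_LEVEL)
    params = build_params(raw.get("params") or {})
    run = raw.get("run") or {}
    _check_keys("run", run, _RUN_FIELDS)
    for key in run:
        v = run[key]
        if not 0.0 <= float(v) <= 1.0:
            raise ValueError(f"run.{key} must be in [0, 1]; got {v}")
    grad_raw = raw.get("gradient") or {}
    _check_keys("gradient", grad_raw, _GRADIENT_FIELDS)
    gradient = GradientSettings(**grad_raw)
    return RunConfig(params=params,
                     gamma_t0=float(run.get("gamma_t0", 0.5)),
                     gamma_r=float(run.get("gamma_r", 0.5)),
                     gradient=gradient,
                     sweep=raw.get("sweep"))


def save_config(config: RunConfig, path: str | Path) -> None:
    """Write a config back to YAML (round-trips through load_config)."""
    data: dict[str, Any] = {
        "params": config.params.to_dict(),
        "run": {"gamma_t0": config.gamma_t0, "gamma_r": config.gamma_r},
        "gradient": dataclasses.asdict(config.gradient),
    }
    if config.sweep is not None:
        data["sweep"] = config.sweep
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


__all__ = ["RunConfig", "build_params", "default_params", "load_config",
           "save_config"]
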