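"""Run configuration: a small YAML/JSON schema tying models to methods.

Schema (all keys except ``model`` optional)::

    model: predator_prey
    fixed: {grassregrowthtime: 25}          # parameter overrides
    factors:                                # swept inputs with ranges
      - {name: sheepgainfromfood, min: 2, max: 8}
    method:                                 # method settings (subcommand-specific)
      ticks: 200
      replications: 2
      levels: 5           # Morris p
      trajectories: 10    # Morris r
      samples: 64         # Sobol N / stability s / calibration n
      maxreps: 50         # stability r_max
      checkpoints: [5, 10, 15]
      tol: 0.01
      objective: {output: sheep, target: 120}   # calibration cost
    seed: 1
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Any

import yaml

from .design import FactorTable
from .errors import ConfigError, UnknownParameter
from .experiment import Model
from .registry import get_model

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    model_name: str
    model: Model
    fixed: dict[str, Any] = field(default_factory=dict)
    factors: FactorTable = field(default_factory=FactorTable)
    method: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def defaults_with_fixed(self) -> dict[str, Any]:
        params = self.model.declared_parameters()
        params.update(self.fixed)
        return params


def _require_mapping(data: Any, path: str) -> dict:
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping, got {type(data).__name__}")
    return data


def load_config(path: str) -> RunConfig:
    """Parse and validate a YAML (or JSON) run configuration."""
    if not os.path.exists(path):
        raise ConfigError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"{path}: malformed config: {exc}") from exc
    data = _require_mapping(data, path)

    name = data.get("model")
    if not name:
        raise ConfigError(f"{path}: missing required key 'model'")
    model = get_model(str(name))
    declared = model.declared_parameters()

    fixed = data.get("fixed") or {}
    if not isinstance(fixed, dict):
        raise ConfigError(f"{path}: 'fixed' must be a mapping")
    for key in fixed:
        if key not in declared:
            raise UnknownParameter(
                f"{path}: fixed parameter {key!r} is not declared by model {name!r}"
            )

    table = FactorTable()
    for i, item in enumerate(data.get("factors") or []):
        if not isinstance(item, dict) or "name" not in item:
            raise ConfigError(f"{path}: factors[{i}] must be a mapping with a 'name'")
        fname = str(item["name"])
        if fname not in declared:
            raise UnknownParameter(
                f"{path}: factor {fname!r} is not declared by model {name!r}"
            )
        try:
            lo = float(item.get("min", item.get("lower")))
            hi = float(item.get("max", item.get("upper")))
        except (TypeError, ValueError):
            raise ConfigError(
                f"{path}: factors[{i}] ({fname!r}) needs numeric min and max"
            ) from None
        table = table.add(fname, lo, hi)

    method = data.get("method") or {}
    if not isinstance(method, dict):
        raise ConfigError(f"{path}: 'method' must be a mapping")

    seed = data.get("seed", 0)
    try:
        seed = int(seed)
    except (TypeError, ValueError):
        raise ConfigError(f"{path}: 'seed' must be an integer") from None

    return RunConfig(
        model_name=str(name),
        model=model,
        fixed=dict(fixed),
        factors=table,
        method=dict(method),
        seed=seed,
    )
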