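"""YAML run-configuration parsing and validation.

A config file is a mapping of parameter blocks, one per component, each
validated against the fields of the corresponding dataclass before any
computation runs; unknown keys are rejected outright so typos fail fast.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

from .exceptions import InvalidParameterError, SchemaError
from .synthetic import ScenarioConfig, SyntheticSpec
from .watercolumn import EcoParams

__all__ = ["RunConfig", "load_config"]

_BLOCKS = {
    "scenario": ScenarioConfig,
    "eco": EcoParams,
    "synthetic": SyntheticSpec,
}
_TOP_KEYS = {"seed", "years", "dt", "n_layers", "verbosity"} | set(_BLOCKS)


@dataclasses.dataclass
class RunConfig:
    """Validated top-level run configuration."""

    seed: int = 0
    years: float = 3.0
    dt: float = 0.05
    n_layers: int = 20
    verbosity: int = 0
    scenario: ScenarioConfig = dataclasses.field(default_factory=ScenarioConfig)
    eco: EcoParams = dataclasses.field(default_factory=EcoParams)
    synthetic: SyntheticSpec = dataclasses.field(default_factory=SyntheticSpec)

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.years <= 0 or self.n_layers < 2:
            raise InvalidParameterError("dt, years must be > 0 and n_layers >= 2")
        if int(self.seed) != self.seed or not 0 <= int(self.seed) < 2**31:
            raise InvalidParameterError("seed must be an integer in [0, 2^31)")


def _build_block(cls, mapping: dict[str, Any], block: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - valid
    if unknown:
        raise SchemaError(f"unknown keys in {block!r} block: {sorted(unknown)}")
    return cls(**mapping)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run config; unknown keys raise SchemaError."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise SchemaError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise SchemaError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {
        k: v for k, v in raw.items() if k not in _BLOCKS
    }
    for block, cls in _BLOCKS.items():
        if block in raw:
            if not isinstance(raw[block], dict):
                raise SchemaError(f"config block {block!r} must be a mapping")
            kwargs[block] = _build_block(cls, raw[block], block)
    return RunConfig(**kwargs)
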