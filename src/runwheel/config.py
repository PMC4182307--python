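"""YAML configuration files mirroring :class:`~runwheel.sim.SimConfig`.

A config file is a nested mapping with one section per parameter block
(``trajectory``, ``bouts``, ``rotarod``, ``weight``, ``clinical``,
``survival``) plus the top-level cohort fields. ``dump_yaml`` writes the
documented defaults for any preset; ``load_yaml`` rebuilds a validated
SimConfig, so presets can be exported, edited and re-run. ``.inf`` is the
YAML spelling for parameters that are disabled (e.g. no clinical onset in
healthy animals).
"""

from __future__ import annotations

from dataclasses import asdict, fields
from pathlib import Path

import yaml

from .sim import (
    BoutParams,
    ClinicalParams,
    RotarodParams,
    SimConfig,
    SurvivalParams,
    TrajectoryParams,
    WeightParams,
)

_SECTIONS = {
    "trajectory": TrajectoryParams,
    "bouts": BoutParams,
    "rotarod": RotarodParams,
    "weight": WeightParams,
    "clinical": ClinicalParams,
    "survival": SurvivalParams,
}


def to_dict(config: SimConfig) -> dict:
    """Plain nested-dict form of a SimConfig (YAML/JSON serializable)."""
    return asdict(config)


def from_dict(data: dict) -> SimConfig:
    """Build a validated SimConfig from a nested mapping.

    Unknown keys raise, naming the offending field.
    """
    data = dict(data)
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = data.pop(name, None)
        if section is None:
            continue
        allowed = {f.name for f in fields(cls)}
        unknown = set(section) - allowed
        if unknown:
            raise ValueError(f"unknown keys in section '{name}': {sorted(unknown)}")
        kwargs[name] = cls(**section)
    allowed = {f.name for f in fields(SimConfig)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs.update(data)
    return SimConfig(**kwargs)


def dump_yaml(config: SimConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(to_dict(config), sort_keys=False))
    return path


def load_yaml(path: str | Path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    return from_dict(data)
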