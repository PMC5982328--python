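"""YAML run configuration with strict schema validation.

A run configuration bundles the generator, DTW/vote, classifier and
evaluation options.  Unknown keys are rejected rather than ignored so that
typos in config files fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .evaluation import ScenarioConfig
from .recognition import VoteConfig
from .synth import PopulationConfig, ShapeVariation, WithinStrideNoise


@dataclass
class RunConfig:
    population: PopulationConfig = field(default_factory=PopulationConfig)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    classifier: str = "svm"
    seed: int = 0


_NESTED = {
    "between": ShapeVariation,
    "within": WithinStrideNoise,
    "vote": VoteConfig,
    "population": PopulationConfig,
    "scenario": ScenarioConfig,
}


def _build(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ValueError(f"{context}: expected a mapping, got {type(data).__name__}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"{context}: unknown key(s) {sorted(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if key in _NESTED and isinstance(value, dict):
            kwargs[key] = _build(_NESTED[key], value, f"{context}.{key}")
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    if raw is None:
        return RunConfig()
    return _build(RunConfig, raw, "config")


def dump_config(config: RunConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(dataclasses.asdict(config), sort_keys=False), encoding="utf-8"
    )
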