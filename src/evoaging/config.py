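"""Run configuration: a single YAML file validated into typed blocks.

A run file has up to four blocks — ``hazard`` (mortality law), ``evolution``
(population and algorithm parameters), ``analysis`` (binning and shape
thresholds) and ``experiment`` (scan grids and stress specifications).
Unknown keys are rejected so silent typos cannot change a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .experiments import DEFAULT_A, DEFAULT_PM_GRID, default_b_grid
from .hazards import HazardFamily, HazardParams
from .stochastic import EvolutionConfig

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or unreadable run configuration."""


@dataclass
class AnalysisConfig:
    bins: int = 100
    include_oldest_old: bool = False
    min_exposure: float = 0.0
    theta0: float = 0.1
    theta1: float = 0.5
    delta: float = 0.5


@dataclass
class ExperimentConfig:
    b_values: tuple = ()        # empty: use the family/engine default grid
    pm_values: tuple = DEFAULT_PM_GRID
    x_split: float = 0.3
    x_tail: float = 0.6
    stress_b_values: tuple = ()
    shock_b_factor: float = 10.0


_HAZARD_DEFAULTS = {"family": "HRM", "a": DEFAULT_A[HazardFamily.HRM],
                    "b": default_b_grid(HazardFamily.HRM)[2],
                    "k": 1.0, "ext": 0.0}


def _build(cls, block: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in [{name}]: {sorted(unknown)}")
    try:
        return cls(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid [{name}] block: {exc}") from exc


@dataclass
class RunConfig:
    """Validated configuration for a whole run."""

    hazard: HazardParams = field(
        default_factory=lambda: HazardParams(**_HAZARD_DEFAULTS))
    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigError("configuration root must be a mapping")
        unknown = set(data) - {"hazard", "evolution", "analysis", "experiment"}
        if unknown:
            raise ConfigError(f"unknown top-level block(s): {sorted(unknown)}")
        hz = dict(_HAZARD_DEFAULTS)
        hz_block = dict(data.get("hazard", {}))
        unknown = set(hz_block) - set(hz)
        if unknown:
            raise ConfigError(f"unknown key(s) in [hazard]: {sorted(unknown)}")
        hz.update(hz_block)
        try:
            hazard = HazardParams(**hz)
        except ValueError as exc:
            raise ConfigError(f"invalid [hazard] block: {exc}") from exc
        evo_block = {k: (tuple(v) if isinstance(v, list) else v)
                     for k, v in dict(data.get("evolution", {})).items()}
        evolution = _build(EvolutionConfig, evo_block, "evolution")
        analysis = _build(AnalysisConfig, dict(data.get("analysis", {})),
                          "analysis")
        exp_block = {k: (tuple(v) if isinstance(v, list) else v)
                     for k, v in dict(data.get("experiment", {})).items()}
        experiment = _build(ExperimentConfig, exp_block, "experiment")
        return cls(hazard=hazard, evolution=evolution, analysis=analysis,
                   experiment=experiment)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        try:
            data = yaml.safe_load(path.read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        def plain(obj):
            d = dataclasses.asdict(obj)
            return {k: (v.value if isinstance(v, HazardFamily)
                        else list(v) if isinstance(v, tuple) else v)
                    for k, v in d.items()}

        return {"hazard": plain(self.hazard),
                "evolution": plain(self.evolution),
                "analysis": plain(self.analysis),
                "experiment": plain(self.experiment)}

    def digest(self) -> str:
        """Short stable hash of the full configuration (for provenance)."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)
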