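"""Run configuration: one plain-YAML file driving all three stages.

Defaults reproduce the reference experiment (100 mg predator on 1 mg prey,
1 h trials, 5 replicates per density, the standard allometric trait
constants and ODE environment).  The configuration round-trips losslessly
through YAML and hashes deterministically for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .allometry import AllometricConstants
from .ibm import DESK_AREAS, DESK_REFUGES, FULL_AREAS, FULL_REFUGES
from .odepop import EnvironmentSpec

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


@dataclass
class RunConfig:
    """Everything needed to rerun the simulate -> fit -> map pipeline."""

    areas: list[float] = field(default_factory=lambda: list(DESK_AREAS))
    refuge_fractions: list[float] = field(default_factory=lambda: list(DESK_REFUGES))
    reps: int = 5
    max_feeding_reps: int = 50
    n_steps: int = 3600
    predator_mass: float = 100.0
    prey_mass: float = 1.0
    satiation_fraction: float = 0.9
    max_exponent: int = 24
    seed: int = 0
    assimilation_efficiency: float = 0.85
    foraging_time_proportion: float = 0.5
    allometry: AllometricConstants = field(default_factory=AllometricConstants)
    environment: EnvironmentSpec = field(default_factory=EnvironmentSpec)

    @classmethod
    def full_scale(cls, **overrides) -> "RunConfig":
        """The full factorial: 12 patch sizes, 5%-75% refuge in 5% steps."""
        return cls(
            areas=list(FULL_AREAS), refuge_fractions=list(FULL_REFUGES), **overrides
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "allometry" in d and isinstance(d["allometry"], dict):
            d["allometry"] = AllometricConstants(**d["allometry"])
        if "environment" in d and isinstance(d["environment"], dict):
            d["environment"] = EnvironmentSpec(**d["environment"])
        return cls(**d)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(payload)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the canonicalised configuration."""
    canon = json.dumps(config.to_dict(), sort_keys=True, default=float)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
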