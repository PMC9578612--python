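"""Run configuration: every decision knob, schema-validated from YAML."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    # data_io
    score_min: float = 400.0
    # scoring
    scheme: str = "diffusion"
    scope: str = "local"
    walk_steps: int | None = None
    diffusion_ratio: bool = False
    # clustering
    k_max: int = 10
    hartigan_threshold: float = 10.0
    hartigan_rule: str = "argmin"
    kmeans_restarts: int = 10
    nonnegative_eigs_only: bool = False
    # pair selection
    min_samples: int = 3
    order_policy: str = "min"
    # association
    bliss_threshold: float = 0.12
    # global
    seed: int = 0

    def __post_init__(self):
        if self.scheme not in ("most_probable", "random_walk", "diffusion"):
            raise ConfigError(f"unknown scheme {self.scheme!r}")
        if self.scope not in ("local", "global"):
            raise ConfigError(f"unknown scope {self.scope!r}")
        if self.hartigan_rule not in ("argmin", "threshold"):
            raise ConfigError(f"unknown hartigan_rule {self.hartigan_rule!r}")
        if self.order_policy != "min":
            raise ConfigError("only the 'min' order policy is supported")
        if self.k_max < 1:
            raise ConfigError("k_max must be >= 1")
        if self.min_samples < 2:
            raise ConfigError("min_samples must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
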