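"""YAML experiment configuration: schema validation and defaults.

A config file selects the protocol, geometry preset and any synaptic or
simulation overrides.  Defaults are the standard cellular/synaptic tables;
unknown keys are rejected with the path to the offending key, and the
swept global-inhibition amplitudes are range-checked against [0, 30] nS.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

from .network import SynapseParams

_PROTOCOLS = ("contrast-sweep", "state-map", "staged", "slow-osc",
              "multi-item", "conjunction", "robustness")

__all__ = ["ExperimentConfig", "load_config", "save_config", "config_hash"]


@dataclass
class ExperimentConfig:
    protocol: str = "contrast-sweep"
    scale: str = "desk"
    seed: int = 0
    repeats: int | None = None
    duration: float | None = None
    dt: float = 1.0
    variant: str | None = None   # slow-osc variant / conjunction mode / panel
    syn: SynapseParams = field(default_factory=SynapseParams)
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.protocol not in _PROTOCOLS:
            raise ValueError(f"protocol: unknown protocol {self.protocol!r}")
        if self.scale not in ("full", "desk"):
            raise ValueError(f"scale: unknown preset {self.scale!r}")
        if self.dt <= 0:
            raise ValueError("dt: must be positive")
        self.syn.validate()


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment config.

    Unknown keys raise with their path; ``syn`` entries override the default
    synaptic table (e.g. ``syn: {ge_lower_amp: 12}``)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    known = {f.name for f in fields(ExperimentConfig)}
    for key in data:
        if key not in known:
            raise ValueError(f"unknown config key: {key}")
    syn_data = data.pop("syn", {}) or {}
    syn_known = set(SynapseParams.__dataclass_fields__)
    for key in syn_data:
        if key not in syn_known:
            raise ValueError(f"unknown config key: syn.{key}")
    cfg = ExperimentConfig(**data, syn=SynapseParams(**syn_data))
    cfg.validate()
    return cfg


def save_config(cfg: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=True)


def config_hash(cfg: ExperimentConfig) -> str:
    """Stable hash of the canonicalised config."""
    canon = yaml.safe_dump(asdict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
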