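"""Experiment configuration: one validated object drives a full run.

The default configuration is desk-scale: a 12x12x12 voxel grid with one
40-voxel shared (supramodal) cluster and 30-voxel auditory / visual /
motor clusters, action effect 1.0 in every set, noise SD 0.5 — strong,
compact signal suited to feature-recovery experiments. Two preset
variants change only the effect sizes:

* ``modality_dominant`` — no shared signal (shared effect 0), moderate
  modality-specific effects; within-condition decoding works but
  nothing transfers across modalities.
* ``shared_signal`` — a dominant shared effect with weaker
  modality-specific effects; the regime in which the knock-out analyses
  show their signature (exclusion hurts, restriction generalises).

The cluster-correction minimum is grid-proportional at desk scale (5
voxels on 12^3); brain-scale runs should use the conventional 150.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, replace

import yaml

from .rfe import RFEConfig
from .synthetic import DesignSpec, GROUND_TRUTH_SETS


@dataclass(frozen=True)
class StatsConfig:
    n_perm: int = 99
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class ExperimentConfig:
    grid_dims: tuple = (12, 12, 12)
    voxel_size_mm: tuple = (2.0, 2.0, 2.0)
    cluster_sizes: dict = field(
        default_factory=lambda: {"shared": 40, "auditory": 30, "visual": 30, "motor": 30}
    )
    effect_size: dict = field(
        default_factory=lambda: {"shared": 1.0, "auditory": 1.0, "visual": 1.0, "motor": 1.0}
    )
    design: DesignSpec = field(default_factory=DesignSpec)
    target_per_class: int = 20
    scaling: str = "pooled"
    rfe: RFEConfig = field(default_factory=lambda: RFEConfig(min_cluster_voxels=5))
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scaling not in ("pooled", "per_fold"):
            raise ValueError("scaling must be 'pooled' or 'per_fold'")
        if self.target_per_class < 1:
            raise ValueError("target_per_class must be >= 1")
        unknown = (set(self.cluster_sizes) | set(self.effect_size)) - set(GROUND_TRUTH_SETS)
        if unknown:
            raise ValueError(f"unknown ground-truth set names {sorted(unknown)}")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid_dims"] = list(self.grid_dims)
        d["voxel_size_mm"] = list(self.voxel_size_mm)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")

        def build(sub_cls, value):
            if value is None:
                return sub_cls()
            sub_known = {f.name for f in dataclasses.fields(sub_cls)}
            bad = set(value) - sub_known
            if bad:
                raise ValueError(f"unknown {sub_cls.__name__} keys: {sorted(bad)}")
            return sub_cls(**value)

        if "design" in data:
            data["design"] = build(DesignSpec, data["design"])
        if "rfe" in data:
            data["rfe"] = build(RFEConfig, data["rfe"])
        if "stats" in data:
            data["stats"] = build(StatsConfig, data["stats"])
        for key in ("grid_dims", "voxel_size_mm"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def with_seed(self, seed: int) -> "ExperimentConfig":
        return replace(self, seed=int(seed), design=replace(self.design, seed=int(seed)))


def default_config(seed: int = 0) -> ExperimentConfig:
    """Desk-scale config with effect 1.0 in every informative set."""
    return ExperimentConfig().with_seed(seed)


def modality_dominant_config(seed: int = 0) -> ExperimentConfig:
    """Modality-specific signal only: nothing shared across modalities."""
    cfg = ExperimentConfig(
        effect_size={"shared": 0.0, "auditory": 0.25, "visual": 0.25, "motor": 0.25}
    )
    return cfg.with_seed(seed)


def shared_signal_config(seed: int = 0) -> ExperimentConfig:
    """Dominant shared (supramodal) signal, weaker modality-specific."""
    cfg = ExperimentConfig(
        effect_size={"shared": 0.3, "auditory": 0.15, "visual": 0.15, "motor": 0.15}
    )
    return cfg.with_seed(seed)


PRESETS = {
    "default": default_config,
    "modality_dominant": modality_dominant_config,
    "shared_signal": shared_signal_config,
}
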