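"""Pipeline configuration: every stage's parameters in one YAML-mappable tree.

Defaults equal the reference design throughout: 800 x 150 px 8-bit frames
at 500 fps, detection threshold 5 with minimum area 50, 50 x 50 clips,
tau = alpha = 8 and beta = 1/8 for the classifier, SGD momentum 0.9 with
batch size 8, validation every 2 epochs, at most 250 epochs, dropout 0.5,
five donor-disjoint splits. Unknown keys in a YAML file are rejected.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, fields, asdict, is_dataclass
from pathlib import Path

import yaml

from .slowfast import SlowFastConfig
from .synthetic import SceneParams
from .training import TrainConfig

__all__ = ["PipelineConfig", "CohortConfig", "DetectionConfig",
           "TrackingConfig", "EvalConfig", "load_config", "dump_config",
           "config_hash"]


@dataclass(frozen=True)
class CohortConfig:
    """Synthetic cohort layout: donors per class and cells per donor."""

    n_fetal: int = 6
    n_adult: int = 6
    cells_per_donor: int = 30
    donor_effect_sd: float = 0.05
    fetal_area_scale: float | None = None    # override the 1.21**(2/3) ratio
    fetal_deformation_amplitude: float | None = None
    adult_deformation_amplitude: float | None = None


@dataclass(frozen=True)
class DetectionConfig:
    threshold: float = 5.0
    min_area: int = 50
    sigma: float = 1.0
    connectivity: int = 8
    n_background_samples: int = 100


@dataclass(frozen=True)
class TrackingConfig:
    min_track_len: int = 8
    clip_size: int = 50
    clip_frames: int = 64


@dataclass(frozen=True)
class EvalConfig:
    n_splits: int = 5
    stratify_splits: bool = False   # per-class greedy balancing
    mode: str = "cv"            # "cv": 4 fold models; "single": one model
    run_donor_stats: bool = True
    run_ramping: bool = False
    ramping_fractions: tuple = tuple((i + 1) / 10 for i in range(10))


@dataclass(frozen=True)
class PipelineConfig:
    scene: SceneParams = field(default_factory=SceneParams)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    model: SlowFastConfig = field(default_factory=SlowFastConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    seed: int = 0

    def __post_init__(self):
        if self.model.clip_frames != self.tracking.clip_frames:
            raise ValueError(
                "model.clip_frames must equal tracking.clip_frames")
        if self.model.clip_size != self.tracking.clip_size:
            raise ValueError("model.clip_size must equal tracking.clip_size")


def _build(cls, data: dict):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"section for {cls.__name__} must be a mapping")
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(
            f"unknown keys {sorted(unknown)} in section {cls.__name__}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        sub = _SECTION_TYPES.get((cls, name))
        kwargs[name] = _build(sub, value) if sub is not None else (
            tuple(value) if isinstance(value, list) else value)
    return cls(**kwargs)


_SECTION_TYPES = {
    (PipelineConfig, "scene"): SceneParams,
    (PipelineConfig, "cohort"): CohortConfig,
    (PipelineConfig, "detection"): DetectionConfig,
    (PipelineConfig, "tracking"): TrackingConfig,
    (PipelineConfig, "model"): SlowFastConfig,
    (PipelineConfig, "training"): TrainConfig,
    (PipelineConfig, "evaluation"): EvalConfig,
}


def load_config(path: str | Path | None = None, data: dict | None = None) -> PipelineConfig:
    """Load and validate a pipeline configuration from YAML or a dict.

    Absent sections and keys take the reference defaults."""
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    return _build(PipelineConfig, data or {})


def _jsonable(obj):
    if is_dataclass(obj):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_jsonable(v) for v in obj]
    return obj


def dump_config(cfg: PipelineConfig) -> str:
    """Canonical YAML serialization of a configuration."""
    return yaml.safe_dump(_jsonable(cfg), sort_keys=True)


def config_hash(cfg: PipelineConfig) -> str:
    """Stable hash of the canonical configuration serialization."""
    return hashlib.sha256(dump_config(cfg).encode()).hexdigest()[:16]


def desk_config(n_fetal: int = 6, n_adult: int = 6,
                cells_per_donor: int = 30, clip_frames: int = 32,
                max_epochs: int = 30, mode: str = "single",
                seed: int = 0) -> PipelineConfig:
    """A CPU-scale pipeline configuration for synthetic-cohort runs.

    The scene is shrunk (256 x 80 px) and the arrival rate raised so a
    donor recording is a few hundred frames instead of tens of thousands;
    clips keep their 50 x 50 spatial contract at 32 frames, and the
    classifier uses the tiny depth preset with input pooling 2. Training
    is sized for a tiny network on a small cohort: lr 0.02, light dropout
    and weight decay, ±2 px jitter. Detection, tracking-overlap and split
    parameters keep the reference defaults.
    """
    return load_config(data={
        "scene": {"frame_height": 80, "frame_width": 256, "wall_rows": 12,
                  "constriction_extra": 16, "constriction_length": 0.2,
                  "cells_per_s": 20.0},
        "cohort": {"n_fetal": n_fetal, "n_adult": n_adult,
                   "cells_per_donor": cells_per_donor},
        # clips must span the constriction passage: fragments shorter than
        # half a crossing carry no deformation signal
        "tracking": {"clip_frames": clip_frames, "min_track_len": 24},
        "model": {"clip_frames": clip_frames, "depth": "tiny",
                  "dropout": 0.1, "spatial_pool": 2},
        "training": {"max_epochs": max_epochs, "lr": 0.02,
                     "weight_decay": 1e-4, "jitter_px": 2,
                     "temporal_jitter": 2, "patience": 10,
                     "mixup_alpha": 0.3, "swa": True},
        "evaluation": {"mode": mode, "stratify_splits": True},
        "seed": seed,
    })
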