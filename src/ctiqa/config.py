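"""Run configuration: a YAML file with data / model / train / eval / io sections.

Unknown keys are rejected so typos fail loudly; every run's effective config
is persisted beside its outputs.  Sections translate into the library's
dataclasses (:class:`~ctiqa.model.ModelSpec`, :class:`~ctiqa.model.TrainConfig`,
corpus generator arguments) via the builder helpers below.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .backbone import BackboneConfig, PAPER_BACKBONE, TINY_BACKBONE
from .corpus import MixtureConfig, ScoreRange
from .kan import SplineGrid
from .model import ModelSpec, TrainConfig
from .swin import PAPER_SCHEDULE, StageSchedule, TINY_SCHEDULE

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class DataSection:
    domain: str = "target"
    n_pristine: int = 81
    n_types: int = 25
    n_levels: int = 5
    n_slices: int = 200
    size: int = 64
    seed: int = 0
    jitter_sd: float = 0.1
    image_format: str = "png"


@dataclass
class ModelSection:
    preset: str = "tiny"  # tiny | paper
    combination: str = "mkca"
    kan_heads: int = 16
    attn_heads: int = 4
    window: int | None = None
    grid_side: int | None = None
    kan_grid_intervals: int = 5
    kan_grid_order: int = 3
    clip_scores_at_inference: bool = True
    tta: bool = False


@dataclass
class TrainSection:
    epochs_pretrain: int = 8
    epochs_finetune: int = 30
    batch_size: int = 4
    learning_rate: float = 1e-3
    lr_floor: float = 1e-6
    seed: int = 0
    freeze_backbone: bool = False
    loss_reduction: str = "sum"
    select_best_val: bool = False


@dataclass
class EvalSection:
    split: str = "test"
    plots: bool = False


@dataclass
class IOSection:
    out_dir: str = "runs"
    image_format: str = "png"


@dataclass
class RunConfig:
    data: DataSection = field(default_factory=DataSection)
    model: ModelSection = field(default_factory=ModelSection)
    train: TrainSection = field(default_factory=TrainSection)
    eval: EvalSection = field(default_factory=EvalSection)
    io: IOSection = field(default_factory=IOSection)

    def model_spec(self) -> ModelSpec:
        m = self.model
        if m.preset == "tiny":
            backbone, schedule, grid_side = TINY_BACKBONE, TINY_SCHEDULE, 16
        elif m.preset == "paper":
            backbone, schedule, grid_side = PAPER_BACKBONE, PAPER_SCHEDULE, 64
        else:
            raise ValueError(f"unknown model preset {m.preset!r}")
        schedule = replace(
            schedule,
            combination=m.combination,
            kan_heads=m.kan_heads,
            attn_heads=m.attn_heads,
            kan_grid=SplineGrid(intervals=m.kan_grid_intervals, order=m.kan_grid_order),
            **({"window": m.window} if m.window else {}),
        )
        return ModelSpec(
            backbone=backbone,
            schedule=schedule,
            grid_side=m.grid_side or grid_side,
            clip_scores_at_inference=m.clip_scores_at_inference,
            tta=m.tta,
        )

    def train_config(self, phase: str) -> TrainConfig:
        t = self.train
        return TrainConfig(
            phase=phase,
            epochs=t.epochs_pretrain if phase == "pretrain" else t.epochs_finetune,
            batch_size=t.batch_size,
            learning_rate=t.learning_rate,
            lr_floor=t.lr_floor,
            seed=t.seed,
            freeze_backbone=t.freeze_backbone and phase == "finetune",
            loss_reduction=t.loss_reduction,
            select_best_val=t.select_best_val,
        )

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "data": DataSection,
    "model": ModelSection,
    "train": TrainSection,
    "eval": EvalSection,
    "io": IOSection,
}


def load_config(path) -> RunConfig:
    """Parse a YAML run config; unknown sections or keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("run config must be a mapping of sections")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        body = raw.get(name, {}) or {}
        allowed = {f.name for f in fields(cls)}
        bad = set(body) - allowed
        if bad:
            raise ValueError(f"unknown key(s) in section {name!r}: {sorted(bad)}")
        kwargs[name] = cls(**body)
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
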