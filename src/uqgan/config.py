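"""Serializable run configuration tying all sub-configs together.

A ``RunConfig`` captures everything needed to reproduce a run given its
seed: the task, the phantom composition, the dropout / objective / training
settings, and report options.  Round-trips through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .networks import DiscriminatorSpec, DropoutConfig, GeneratorSpec
from .objectives import ObjectiveConfig
from .synthetic_data import ImbalanceSpec, ShiftSpec
from .training import TrainConfig

__all__ = ["RunConfig"]

TASKS = ("segmentation", "classification", "ood")


def _tupled(d: dict, keys: tuple[str, ...]) -> dict:
    return {k: tuple(v) if k in keys and isinstance(v, list) else v
            for k, v in d.items()}


@dataclass
class RunConfig:
    task: str = "segmentation"
    seed: int = 0
    n_images: int = 200
    imbalance: ImbalanceSpec = field(default_factory=ImbalanceSpec)
    shift: ShiftSpec = field(default_factory=ShiftSpec)
    generator: GeneratorSpec = field(default_factory=GeneratorSpec)
    discriminators: tuple[DiscriminatorSpec, ...] = (
        DiscriminatorSpec(loss_type="mae"),
        DiscriminatorSpec(loss_type="cce"),
        DiscriminatorSpec(loss_type="dice"),
    )
    train: TrainConfig = field(default_factory=TrainConfig)
    ece_bins: int = 10
    spacing: float = 1.0

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["discriminators"] = [asdict(s) for s in self.discriminators]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        imb = dict(d.get("imbalance", {}))
        if imb:
            imb = _tupled(imb, ("class_names", "target_ratios", "image_size",
                                "lesion_size_range"))
            if "intensity_model" in imb:
                imb["intensity_model"] = tuple(tuple(p)
                                               for p in imb["intensity_model"])
            d["imbalance"] = ImbalanceSpec(**imb)
        else:
            d["imbalance"] = ImbalanceSpec()
        d["shift"] = ShiftSpec(**d["shift"]) if "shift" in d else ShiftSpec()
        d["generator"] = GeneratorSpec(**d["generator"]) \
            if "generator" in d else GeneratorSpec()
        d["discriminators"] = tuple(
            DiscriminatorSpec(**s) for s in d.get("discriminators", [])) \
            or RunConfig.__dataclass_fields__["discriminators"].default
        tr = dict(d.get("train", {}))
        if "dropout" in tr:
            tr["dropout"] = DropoutConfig(**tr["dropout"])
        if "objective" in tr:
            tr["objective"] = ObjectiveConfig(**_tupled(
                tr["objective"],
                ("lambda_k", "loss_assignment", "mode_probs", "aux_weights")))
        d["train"] = TrainConfig(**tr) if tr else TrainConfig()
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
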