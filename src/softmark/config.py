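"""Run configuration: one flat document tying all stage settings together.

Every default equals the reference protocol (98 subjects, 68/15/15
subject split, brightness jitter in [0.7, 1.3] doubling the training
set, Adam 1e-4 / batch 16 / 50 epochs / patience 10, 0.1 mm/pixel,
+/-2 mm equivalence margin); departures are explicit keys.  A run's
config is archived alongside its outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Any

import yaml

from .equivalence import EquivalenceConfig
from .model import TrainConfig
from .pipeline import AugmentationConfig
from .synthetic import DEFAULT_JITTER_SD_MM


@dataclass
class RunConfig:
    master_seed: int = 42
    n_subjects: int = 98
    split_sizes: tuple[int, int, int] = (68, 15, 15)
    split_seed: int = 42
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    base_scale_mm_per_px: float = 0.1
    jitter_sd_mm: float = DEFAULT_JITTER_SD_MM
    icc_subset_size: int = 20  # images re-annotated for the ICC protocol
    equivalence: EquivalenceConfig = field(default_factory=EquivalenceConfig)
    views: tuple[str, ...] = ("frontal", "profile")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["split_sizes"] = list(self.split_sizes)
        d["views"] = list(self.views)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "augmentation" in d and isinstance(d["augmentation"], dict):
            d["augmentation"] = AugmentationConfig(**d["augmentation"])
        if "train" in d and isinstance(d["train"], dict):
            d["train"] = TrainConfig(**d["train"])
        if "equivalence" in d and isinstance(d["equivalence"], dict):
            d["equivalence"] = EquivalenceConfig(**d["equivalence"])
        if "split_sizes" in d:
            d["split_sizes"] = tuple(d["split_sizes"])
        if "views" in d:
            d["views"] = tuple(d["views"])
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
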