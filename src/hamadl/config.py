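"""Pipeline configuration: centralized defaults, YAML loading, validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import yaml

from .errors import DataError

CODEBOOK_SIZES = (16, 32, 64, 128, 256, 512)
MODEL_SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """All tunables of the train/detect/evaluate flow.

    fps: frame rate of the trajectory files (frames per second).
    k_high: coarse region count, or "auto" for the BIC sweep.
    multipliers: mid/low region counts as multiples of the coarse count.
    k_stage1: per-subject cluster count of clustering stage 1.
    k_max_auto: upper end of the BIC sweep in auto mode.
    codebook_size: codewords per region codebook (clipped to the data).
    per_region_k: activity classes per region, or "auto" (BIC on histograms).
    max_classes_per_region: cap of the per-region class sweep in auto mode.
    min_stay_frames: stay runs shorter than this are absorbed (1 = off).
    overlap_frac: detection-metric overlap rule (strictly-greater test).
    neutral_label / include_neutral_in_fa: background-class handling.
    seed: master seed threaded through every random stage.
    """

    fps: float = 25.0
    k_high: int | str = "auto"
    multipliers: tuple[int, int] = (2, 3)
    k_stage1: int = 8
    k_max_auto: int = 8
    codebook_size: int = 32
    per_region_k: int | str = "auto"
    max_classes_per_region: int = 4
    min_stay_frames: int = 1
    overlap_frac: float = 0.8
    neutral_label: str = "Neutral"
    include_neutral_in_fa: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise DataError("fps must be positive")
        self.multipliers = tuple(self.multipliers)  # type: ignore[assignment]
        if len(self.multipliers) != 2 or self.multipliers[0] < 1 or self.multipliers[1] < self.multipliers[0]:
            raise DataError(f"invalid multipliers {self.multipliers}")
        if self.k_high != "auto" and int(self.k_high) < 1:
            raise DataError("k_high must be 'auto' or a positive integer")
        if self.codebook_size < 1:
            raise DataError("codebook_size must be >= 1")
        if not 0 < self.overlap_frac <= 1:
            raise DataError("overlap_frac must be in (0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["multipliers"] = list(self.multipliers)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise DataError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise DataError(f"{path}: config must be a mapping")
        return cls.from_dict(data)
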