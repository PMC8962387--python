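"""Pipeline configuration: every tunable knob with its documented default."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All pipeline knobs.  Unknown keys in a config file are rejected.

    Attributes
    ----------
    tr, te : acquisition timing of the dynamic series, seconds.
    trunc_frac : sSVD singular-value truncation threshold, fraction of
        sigma_max in [0, 1).
    aif_mode : "auto" (image-based selection) or "sidecar" (ground-truth AIF
        from the phantom sidecar, available for synthetic cohorts only).
    map_median_radius : median-filter radius applied to the perfusion maps.
    drop_threshold : fractional SWI signal drop defining a cell-positive
        voxel, in (0, 1).
    min_size : minimum 26-connected component size kept in the cell mask.
    kernel_radius : spherical density kernel radius, mm.
    density_median_radius : median-filter radius of the density map.
    registration : run rigid pre/post SWI registration (True) or assume the
        volumes are already aligned (False).
    correlation_mode : "per_animal" (default) or "pooled" voxel pooling.
    only_significant : apply the significance filter when summarizing.
    alpha : significance level.
    seed : base seed for any stochastic stage.
    """

    tr: float = 1.5
    te: float = 0.015
    trunc_frac: float = 0.2
    aif_mode: str = "auto"
    map_median_radius: int = 1
    drop_threshold: float = 0.2
    min_size: int = 2
    kernel_radius: float = 0.45
    density_median_radius: int = 1
    registration: bool = True
    correlation_mode: str = "per_animal"
    only_significant: bool = True
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.tr <= 0 or self.te <= 0:
            raise ValueError("tr and te must be positive")
        if not (0 <= self.trunc_frac < 1):
            raise ValueError("trunc_frac must be in [0, 1)")
        if self.aif_mode not in ("auto", "sidecar"):
            raise ValueError("aif_mode must be 'auto' or 'sidecar'")
        if not (0 < self.drop_threshold < 1):
            raise ValueError("drop_threshold must be in (0, 1)")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.kernel_radius <= 0:
            raise ValueError("kernel_radius must be positive")
        if self.map_median_radius < 0 or self.density_median_radius < 0:
            raise ValueError("median radii must be >= 0")
        if self.correlation_mode not in ("per_animal", "pooled"):
            raise ValueError("correlation_mode must be 'per_animal' or 'pooled'")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)
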