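"""Pipeline configuration with YAML round-tripping."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .postprocess import MorphParams


@dataclass
class PipelineConfig:
    """Everything the batch pipeline needs, in documented ranges.

    ``resize_to`` is ``[width, height]`` (bilinear, applied before
    classification, off by default); ``roi`` is the half-open rectangle
    ``[row_start, row_end, col_start, col_end]``.
    """

    reference_file: str = ""
    images: str = ""
    output_dir: str = "results"
    covariance: str = "per_class"  # or "pooled_image"
    shrinkage: float = 0.1
    representative: str = "centroid"  # or "nearest_reference"
    selem_shape: str = "square"
    selem_size: int = 3
    open_iterations: int = 1
    close_iterations: int = 1
    min_component_px: int = 25
    lower_fraction: float = 0.5
    clean_grape: bool = True
    resize_to: list[int] | None = None
    roi: list[int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.covariance not in ("per_class", "pooled_image"):
            raise ValueError(f"unknown covariance mode {self.covariance!r}")
        if self.representative not in ("centroid", "nearest_reference"):
            raise ValueError(f"unknown representative mode {self.representative!r}")
        if not 0.0 <= self.shrinkage <= 1.0:
            raise ValueError(f"shrinkage must lie in [0, 1], got {self.shrinkage}")
        if not 0.0 < self.lower_fraction <= 1.0:
            raise ValueError(f"lower_fraction must lie in (0, 1], got {self.lower_fraction}")
        if self.resize_to is not None and (
            len(self.resize_to) != 2 or min(self.resize_to) < 1
        ):
            raise ValueError(f"resize_to must be [width, height], got {self.resize_to}")
        if self.roi is not None and len(self.roi) != 4:
            raise ValueError(f"roi must be [row_start, row_end, col_start, col_end]")
        self.morph = MorphParams(
            selem_shape=self.selem_shape,
            selem_size=self.selem_size,
            open_iterations=self.open_iterations,
            close_iterations=self.close_iterations,
            min_component_px=self.min_component_px,
        )

    def to_yaml(self) -> str:
        doc = {f.name: getattr(self, f.name) for f in fields(self)}
        return yaml.safe_dump(doc, sort_keys=True, default_flow_style=None)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        doc = yaml.safe_load(text) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_yaml(Path(path).read_text())

    def save(self, path) -> None:
        Path(path).write_text(self.to_yaml())
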