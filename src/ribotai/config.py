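"""Pipeline configuration: every analysis constant in one overridable place.

The defaults are the pipeline's canonical settings (scan window 21 codons,
>100-codon genome filter, strength threshold 1.3, proximal band 0.16-0.28,
Bonferroni alpha 0.05/61, CGA override 0.1333).  Serializes losslessly to
YAML for run manifests.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    window_n: int = 21
    min_gene_length: int = 101
    strength_threshold: float = 1.3
    proximal_band: tuple[float, float] = (0.16, 0.28)
    alpha: float = 0.05
    bonferroni_divisor: int = 61
    cga_weight: float = 0.1333
    seed: int = 0
    n_variants: int = 150
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.proximal_band = tuple(self.proximal_band)
        if self.window_n < 1 or self.min_gene_length < 1:
            raise ValueError("window_n and min_gene_length must be positive")
        if self.strength_threshold <= 0 or not 0 < self.alpha < 1:
            raise ValueError("strength_threshold must be > 0 and alpha in (0, 1)")
        if self.bonferroni_divisor < 1:
            raise ValueError("bonferroni_divisor must be >= 1")
        if not 0 < self.cga_weight <= 1:
            raise ValueError("cga_weight must be in (0, 1]")
        lo, hi = self.proximal_band
        if not lo < hi:
            raise ValueError("proximal band must satisfy lo < hi")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["proximal_band"] = list(self.proximal_band)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
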