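"""Flat pipeline configuration with screen-standard defaults.

One key-value document collects every tunable of the workflow; unknown keys
are rejected so a typo cannot silently fall back to a default.  The defaults
are the published screen parameters: a [-400, +100] TSS window, six 50-bp
bins, a three-mismatch off-target floor, four guides per 190-bp oligo,
Poisson loading mean 0.4, and the [log2FC > 3, FDR < 0.05] enrichment gate.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    window_upstream: int = 400
    window_downstream: int = 100
    bin_region: int = 300
    bin_width: int = 50
    max_per_feature: int = 6
    pam: str = "NGG"
    min_mismatch: int = 3
    guides_per_oligo: int = 4
    loading_lambda: float = 0.4
    lfc_threshold: float = 3.0
    fdr_threshold: float = 0.05
    gene_fdr_threshold: float = 0.3
    min_cpm: float = 1.0
    min_sample_fraction: float = 0.5
    neighbor_window: int = 1000
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError(f"{path}: config must be a flat mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**doc)

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def overridden(self, **kwargs) -> "PipelineConfig":
        known = {f.name for f in fields(self)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        merged = {**asdict(self), **{k: v for k, v in kwargs.items() if v is not None}}
        return PipelineConfig(**merged)
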