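"""Pipeline configuration: every tunable threshold with its default.

The defaults are the operating points of the analysis: blastp-style hit
cutoff 1e-20, repetitive-gene homolog cutoff >5, WGD dS window [0.5, 0.9],
synonymous rate 2.81e-9 /site/yr, 150/30 bp sliding windows, r^2 < 0.3
expression-divergence rule, Fisher alpha 0.01, 5-fold ratio cutoff, 3 kb
PAR length rule, 30% female-read-fraction cutoff, single-copy depth 20.
Configs load from flat YAML; CLI flags override file values; the effective
config is echoed into every output directory.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    hit_max_evalue: float = 1e-20
    repetitive_homolog_cutoff: int = 5
    wgd_ds_low: float = 0.5
    wgd_ds_high: float = 0.9
    syn_rate_per_year: float = 2.81e-9
    lineage_factor: float = 2.0
    window_bp: int = 150
    step_bp: int = 30
    r2_cutoff: float = 0.3
    fisher_alpha: float = 0.01
    fold_cutoff: float = 5.0
    pseudocount: float = 1.0
    par_min_length_bp: int = 3000
    par_female_fraction: float = 0.30
    male_specific_female_fraction: float = 0.05
    expected_depth: float = 20.0
    depth_window_bp: int = 500
    mode_search_low: float = 0.2
    mode_search_high: float = 2.0
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.hit_max_evalue < 0:
            raise ValueError("hit_max_evalue must be non-negative")
        if self.repetitive_homolog_cutoff < 0:
            raise ValueError("repetitive_homolog_cutoff must be non-negative")
        if not self.wgd_ds_low < self.wgd_ds_high:
            raise ValueError("wgd_ds window requires low < high")
        if self.syn_rate_per_year <= 0:
            raise ValueError("syn_rate_per_year must be positive")
        if self.window_bp % 3 or self.step_bp % 3:
            raise ValueError("window_bp and step_bp must be multiples of 3")
        if not 0 < self.r2_cutoff <= 1:
            raise ValueError("r2_cutoff must be in (0, 1]")
        if not 0 < self.fisher_alpha < 1:
            raise ValueError("fisher_alpha must be in (0, 1)")
        if self.fold_cutoff <= 1:
            raise ValueError("fold_cutoff must exceed 1")
        if self.par_min_length_bp < 0:
            raise ValueError("par_min_length_bp must be non-negative")
        if not 0 <= self.par_female_fraction <= 1:
            raise ValueError("par_female_fraction must be in [0, 1]")
        if self.expected_depth <= 0:
            raise ValueError("expected_depth must be positive")
        if not self.mode_search_low < self.mode_search_high:
            raise ValueError("mode search range requires low < high")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def with_overrides(self, **overrides) -> "PipelineConfig":
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return PipelineConfig(**data)
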