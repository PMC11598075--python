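"""Pipeline configuration: one validated object carrying every stage's
parameters, with defaults fixed to the analysis constants (PE threshold
70%, 1 mm isotropic resampling, 5 mm closing ball, 50 anti-alias
iterations at max RMS 0.01, 100-voxel component floor, 5 inner folds,
20 outer subsamples)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .assembly import ENDPOINTS


@dataclass(frozen=True)
class PipelineConfig:
    # cohort
    n_patients: int = 60
    endpoint: str = "rcb3"
    cohort_overrides: dict = field(default_factory=dict)
    # FTV thresholds
    pe_min: float = 70.0
    ser_min: float = 0.0
    ser_max: float = float("inf")
    # mask conditioning
    target_spacing: float = 1.0
    close_radius: float = 5.0
    aa_iterations: int = 50
    aa_max_rms: float = 0.01
    min_size: int = 100
    connectivity: int = 26
    # evaluation
    n_outer: int = 20
    test_fraction: float = 0.25
    inner_folds: int = 5
    grid_preset: str = "paper"
    imputation: str = "per_split"   # or "whole_table"
    imputer_trees: int = 30
    min_subgroup_events: int = 8
    importance_permutations: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"endpoint must be one of {sorted(ENDPOINTS)}")
        if self.imputation not in ("per_split", "whole_table"):
            raise ValueError("imputation must be 'per_split' or 'whole_table'")
        if self.grid_preset not in ("paper", "fast"):
            raise ValueError("grid_preset must be 'paper' or 'fast'")
        for name in ("pe_min", "target_spacing", "close_radius", "aa_max_rms",
                     "test_fraction"):
            if getattr(self, name) <= 0 and name != "pe_min":
                raise ValueError(f"{name} must be positive")
        if not (0 < self.test_fraction < 1):
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_outer < 1 or self.inner_folds < 2:
            raise ValueError("need >= 1 outer subsample and >= 2 inner folds")
        if self.min_size < 0 or self.n_patients < 1:
            raise ValueError("min_size must be >= 0 and n_patients >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "ser_max" in data and data["ser_max"] in ("inf", ".inf", None):
            data["ser_max"] = float("inf")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        if np.isinf(data["ser_max"]):
            data["ser_max"] = "inf"
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def with_(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)
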