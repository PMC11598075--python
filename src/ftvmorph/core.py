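"""Core containers shared across the pipeline.

Conventions: voxel indices are 0-based, boxes are half-open
``(start, stop)`` per axis, world coordinates and spacings are in mm,
and array axes are ordered (x, y, z) with per-axis spacing aligned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Tuple

import numpy as np

Timepoint = Literal["T0", "T1"]

#: mask conditioning stages, in the only order the pipeline permits
MASK_STAGES = ("raw", "resampled", "closed", "antialiased", "cleaned")


class ShapeMismatchError(ValueError):
    """Volumes that must share a grid do not."""


class DegenerateMaskError(ValueError):
    """Mask too small (or empty) for the requested computation."""


@dataclass(frozen=True)
class TumorMask:
    """Binary tumor mask with physical voxel spacing.

    Parameters
    ----------
    voxels : bool array, 3D
    spacing_mm : per-axis voxel size in mm
    stage : conditioning stage this mask has reached (see MASK_STAGES)
    """

    voxels: np.ndarray
    spacing_mm: Tuple[float, float, float]
    stage: str = "raw"

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={v.ndim}")
        if v.dtype != bool:
            object.__setattr__(self, "voxels", v.astype(bool))
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        if self.stage not in MASK_STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3

    def with_stage(self, voxels: np.ndarray, stage: str,
                   spacing_mm: Tuple[float, float, float] | None = None) -> "TumorMask":
        """Advance to `stage`; transitions must follow MASK_STAGES order."""
        if MASK_STAGES.index(stage) <= MASK_STAGES.index(self.stage):
            raise ValueError(
                f"stage transition {self.stage!r} -> {stage!r} violates pipeline order")
        return TumorMask(voxels=voxels, stage=stage,
                         spacing_mm=self.spacing_mm if spacing_mm is None else spacing_mm)


@dataclass(frozen=True)
class DceExam:
    """One patient-timepoint DCE series: pre, early post and late
    post-contrast volumes on a common grid, plus the volume-of-interest
    box inside which tumor voxels are sought.
    """

    patient_id: str
    timepoint: Timepoint
    s_pre: np.ndarray
    s_early: np.ndarray
    s_late: np.ndarray
    spacing_mm: Tuple[float, float, float]
    voi_box: Tuple[Tuple[int, int], Tuple[int, int], Tuple[int, int]]

    def __post_init__(self):
        shp = self.s_pre.shape
        if self.s_early.shape != shp or self.s_late.shape != shp:
            raise ShapeMismatchError(
                f"exam volumes disagree in shape: {shp}, {self.s_early.shape}, "
                f"{self.s_late.shape}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")
        for ax, ((lo, hi), n) in enumerate(zip(self.voi_box, shp)):
            if not (0 <= lo < hi <= n):
                raise ValueError(
                    f"voi_box {self.voi_box} out of bounds on axis {ax} (size {n})")

    @property
    def grid_shape(self) -> Tuple[int, int, int]:
        return self.s_pre.shape

    def voi_slices(self) -> Tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in self.voi_box)
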