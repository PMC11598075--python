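"""Percent enhancement, signal enhancement ratio, and FTV segmentation.

PE  = 100 * (S_early - S_pre) / S_pre              (percent)
SER = (S_early - S_pre) / (S_late - S_pre)         (unitless)

The functional tumor volume (FTV) is the sum of voxel volumes over the
voxels inside the volume-of-interest box whose PE exceeds a threshold
(default 70%) and whose SER lies inside a configurable band; the default
band [0, inf) applies no SER cut.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .core import DceExam, ShapeMismatchError, TumorMask

#: relative intensity tolerance below which a denominator counts as zero
VALIDITY_EPS = 1e-6

DEFAULT_PE_MIN = 70.0     # percent; segmentation keeps PE strictly above this
DEFAULT_SER_MIN = 0.0
DEFAULT_SER_MAX = np.inf
DEFAULT_SER_CAP = 10.0    # reporting clamp only, not a segmentation cut


@dataclass(frozen=True)
class EnhancementMaps:
    pe: np.ndarray
    ser: np.ndarray
    valid: np.ndarray

    def __post_init__(self):
        if not (self.pe.shape == self.ser.shape == self.valid.shape):
            raise ShapeMismatchError("PE/SER/valid maps disagree in shape")


@dataclass(frozen=True)
class FtvResult:
    ftv_mm3: float
    n_voxels: int
    mask: TumorMask
    pe_min: float
    ser_min: float
    ser_max: float


class UndefinedRatioError(ValueError):
    """FTV ratio requested with a zero pretreatment FTV."""


def _check_shapes(*vols: np.ndarray) -> None:
    shapes = {v.shape for v in vols}
    if len(shapes) != 1:
        raise ShapeMismatchError(f"volumes disagree in shape: {sorted(shapes)}")


def compute_pe(s_pre: np.ndarray, s_early: np.ndarray,
               eps: float = VALIDITY_EPS) -> Tuple[np.ndarray, np.ndarray]:
    """Early percent enhancement and its validity mask.

    Voxels whose pre-contrast signal is at or below ``eps`` times the
    volume's intensity scale are marked invalid rather than divided by.
    """
    _check_shapes(s_pre, s_early)
    scale = max(float(np.abs(s_pre).max()), 1.0)
    valid = s_pre > eps * scale
    pe = np.zeros(s_pre.shape, dtype=float)
    np.divide(s_early - s_pre, s_pre, out=pe, where=valid)
    pe *= 100.0
    return pe, valid


def compute_ser(s_pre: np.ndarray, s_early: np.ndarray, s_late: np.ndarray,
                eps: float = VALIDITY_EPS,
                cap: float = DEFAULT_SER_CAP) -> Tuple[np.ndarray, np.ndarray]:
    """Signal enhancement ratio and its validity mask.

    Voxels with a near-zero late washout denominator |S_late - S_pre|
    are invalid; SER values are clamped to ``cap`` for reporting.
    """
    _check_shapes(s_pre, s_early, s_late)
    denom = s_late - s_pre
    scale = max(float(np.abs(s_pre).max()), 1.0)
    valid = np.abs(denom) > eps * scale
    ser = np.zeros(s_pre.shape, dtype=float)
    np.divide(s_early - s_pre, denom, out=ser, where=valid)
    np.clip(ser, -cap, cap, out=ser)
    return ser, valid


def enhancement_maps(exam: DceExam, eps: float = VALIDITY_EPS) -> EnhancementMaps:
    """PE and SER maps for an exam; valid where both are defined."""
    pe, v1 = compute_pe(exam.s_pre, exam.s_early, eps=eps)
    ser, v2 = compute_ser(exam.s_pre, exam.s_early, exam.s_late, eps=eps)
    return EnhancementMaps(pe=pe, ser=ser, valid=v1 & v2)


def segment_ftv(maps: EnhancementMaps,
                voi_box,
                spacing_mm: Tuple[float, float, float],
                pe_min: float = DEFAULT_PE_MIN,
                ser_min: float = DEFAULT_SER_MIN,
                ser_max: float = DEFAULT_SER_MAX) -> TumorMask:
    """Threshold the enhancement maps inside the VOI box.

    A voxel is selected iff it is valid, its PE is strictly above
    ``pe_min``, its SER lies in [ser_min, ser_max), and it falls inside
    the box. An empty result is allowed (FTV is then zero).
    """
    shape = maps.pe.shape
    for ax, ((lo, hi), n) in enumerate(zip(voi_box, shape)):
        if not (0 <= lo < hi <= n):
            raise ValueError(f"VOI box {voi_box} empty or out of bounds on axis {ax}")
    sel = maps.valid & (maps.pe > pe_min) & (maps.ser >= ser_min) & (maps.ser < ser_max)
    box = np.zeros(shape, dtype=bool)
    box[tuple(slice(lo, hi) for lo, hi in voi_box)] = True
    return TumorMask(voxels=sel & box, spacing_mm=spacing_mm, stage="raw")


def compute_ftv(mask: TumorMask,
                pe_min: float = DEFAULT_PE_MIN,
                ser_min: float = DEFAULT_SER_MIN,
                ser_max: float = DEFAULT_SER_MAX) -> FtvResult:
    """FTV = selected voxel count times the voxel volume (mm^3)."""
    n = mask.n_voxels
    return FtvResult(ftv_mm3=n * mask.voxel_volume_mm3, n_voxels=n, mask=mask,
                     pe_min=pe_min, ser_min=ser_min, ser_max=ser_max)


def exam_ftv(exam: DceExam,
             pe_min: float = DEFAULT_PE_MIN,
             ser_min: float = DEFAULT_SER_MIN,
             ser_max: float = DEFAULT_SER_MAX) -> FtvResult:
    """Full PE/SER -> threshold -> FTV chain for one exam."""
    maps = enhancement_maps(exam)
    mask = segment_ftv(maps, exam.voi_box, exam.spacing_mm,
                       pe_min=pe_min, ser_min=ser_min, ser_max=ser_max)
    return compute_ftv(mask, pe_min=pe_min, ser_min=ser_min, ser_max=ser_max)


def ftv_ratio(ftv_t0_mm3: float, ftv_t1_mm3: float) -> float:
    """FTV_R = FTV(T1) / FTV(T0); undefined (raises) when FTV(T0) = 0.

    Callers treat the undefined case as a missing value routed to
    imputation, never as a sentinel number.
    """
    if ftv_t0_mm3 <= 0:
        raise UndefinedRatioError(
            f"FTV ratio undefined: pretreatment FTV is {ftv_t0_mm3}")
    if ftv_t1_mm3 < 0:
        raise ValueError("negative FTV")
    return ftv_t1_mm3 / ftv_t0_mm3
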