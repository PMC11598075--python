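"""NIfTI / CSV / JSON interchange for exams, masks and results.

Volumes are written one NIfTI file per DCE phase with the voxel spacing
in the affine; a small JSON manifest carries the patient id, timepoint
and VOI box. All voxel indices are 0-based and boxes half-open.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple

import nibabel as nib
import numpy as np

from .core import DceExam, ShapeMismatchError, TumorMask

PHASES = ("s_pre", "s_early", "s_late")
MANIFEST = "exam.json"


class ExamReadError(ValueError):
    """An exam directory is malformed."""


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_exam(exam: DceExam, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for phase in PHASES:
        img = nib.Nifti1Image(getattr(exam, phase).astype(np.float64),
                              _affine(exam.spacing_mm))
        nib.save(img, out / f"{phase}.nii.gz")
    manifest = {"patient_id": exam.patient_id, "timepoint": exam.timepoint,
                "voi_box": [list(b) for b in exam.voi_box],
                "spacing_mm": list(exam.spacing_mm)}
    (out / MANIFEST).write_text(json.dumps(manifest, indent=1))
    return out


def read_exam(exam_dir: str | Path) -> DceExam:
    """Load a written exam; typed errors for missing or inconsistent files."""
    d = Path(exam_dir)
    mpath = d / MANIFEST
    if not mpath.exists():
        raise ExamReadError(f"missing manifest {mpath}")
    manifest = json.loads(mpath.read_text())
    vols = {}
    spacing = None
    for phase in PHASES:
        fpath = d / f"{phase}.nii.gz"
        if not fpath.exists():
            raise ExamReadError(f"missing volume file {fpath}")
        img = nib.load(fpath)
        vols[phase] = np.asarray(img.dataobj, dtype=np.float64)
        sp = tuple(float(z) for z in img.header.get_zooms()[:3])
        if any(s <= 0 for s in sp):
            raise ExamReadError(f"non-positive spacing {sp} in {fpath}")
        if spacing is None:
            spacing = sp
        elif not np.allclose(sp, spacing):
            raise ExamReadError(f"spacing mismatch in {fpath}: {sp} vs {spacing}")
    shapes = {v.shape for v in vols.values()}
    if len(shapes) != 1:
        raise ShapeMismatchError(f"exam volumes disagree in shape: {sorted(shapes)}")
    return DceExam(patient_id=manifest["patient_id"],
                   timepoint=manifest["timepoint"],
                   spacing_mm=spacing,
                   voi_box=tuple(tuple(b) for b in manifest["voi_box"]),
                   **vols)


def write_mask(mask: TumorMask, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(mask.spacing_mm))
    nib.save(img, path)
    return path


def read_mask(path: str | Path, stage: str = "raw") -> TumorMask:
    img = nib.load(path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return TumorMask(voxels=np.asarray(img.dataobj) > 0,
                     spacing_mm=spacing, stage=stage)
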