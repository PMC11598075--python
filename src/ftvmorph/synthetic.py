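"""Synthetic DCE phantom exams and cohorts.

The generator emulates the statistical structure the downstream analysis
assumes: enhancing tumors whose percent enhancement (PE) sits well above
the segmentation threshold while background stays below it; a treatment
effect between the pretreatment (T0) and early-treatment (T1) exams in
which good responders shrink concentrically *and* roughen (their
surface-area-to-volume ratio rises), while poor responders (RCB-III)
largely keep both size and shape; occasional T1 tumors collapsed below
the size at which shape features are computable, so the imputation path
is exercised; and cohort covariate/outcome margins resembling a large
neoadjuvant-chemotherapy trial population.

Tumor geometry is a star-convex solid

    r(theta, phi) = base_radius * (1 + lobulation_amp * P(theta, phi))

with ``P`` a fixed real spherical harmonic of order ``lobulation_order``
normalized to unit peak amplitude, so a single knob controls surface
irregularity (hence SA:V) independently of the volume scale, and
concentric shrinkage by a factor ``s`` has the closed form SA:V -> SA:V/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Tuple

import numpy as np
from scipy.special import sph_harm_y

from .core import DceExam, Timepoint, TumorMask

SUBTYPES = ("HR+/HER2-", "HR+/HER2+", "HR-/HER2+", "HR-/HER2-")
RCB_CLASSES = ("RCB-0", "RCB-I", "RCB-II", "RCB-III")

# Covariate margins emulating a large multicenter neoadjuvant trial cohort.
RACE_LEVELS = ("White", "Black or African American", "Asian", "Mixed",
               "Native Hawaiian or Pacific Islander",
               "American Indian or Alaska Native", "Unknown")
RACE_PROBS = (0.800, 0.114, 0.067, 0.008, 0.005, 0.004, 0.002)
MENOPAUSE_LEVELS = ("Premenopausal", "Perimenopausal", "Postmenopausal",
                    "Not applicable", "Unknown")
MENOPAUSE_PROBS = (0.48, 0.04, 0.31, 0.13, 0.04)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and enhancement kinetics of a single phantom tumor."""

    grid_shape: Tuple[int, int, int] = (48, 48, 48)
    spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    center_mm: Tuple[float, float, float] | None = None  # None -> grid center
    base_radius_mm: float = 10.0
    lobulation_amp: float = 0.0
    lobulation_order: int = 3
    pe_tumor_mean: float = 120.0
    pe_tumor_sd: float = 15.0
    pe_background_mean: float = 10.0
    ser_tumor_mean: float = 1.1
    ser_tumor_sd: float = 0.3
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.lobulation_amp < 1.0):
            raise ValueError("lobulation_amp must lie in [0, 1)")
        if self.lobulation_order < 0:
            raise ValueError("lobulation_order must be >= 0")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacings must be positive")
        if self.base_radius_mm <= 0:
            raise ValueError("base_radius_mm must be positive")

    def resolved_center(self) -> np.ndarray:
        if self.center_mm is not None:
            return np.asarray(self.center_mm, dtype=float)
        return (np.asarray(self.grid_shape) - 1) * np.asarray(self.spacing_mm) / 2.0


_PERTURB_CACHE: Dict[int, float] = {}


def _perturbation(order: int, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Real spherical harmonic of degree `order`, normalized to peak 1.

    Order 0 means no angular perturbation at all (a sphere), not a
    constant inflation — the amplitude knob is then inert by design.
    """
    if order == 0:
        return np.zeros_like(theta)
    m = min(2, order)
    raw = np.real(sph_harm_y(order, m, theta, phi))
    if order not in _PERTURB_CACHE:
        # peak amplitude on a dense fixed reference grid, cached per order
        tg, pg = np.meshgrid(np.linspace(0, np.pi, 181),
                             np.linspace(-np.pi, np.pi, 361), indexing="ij")
        _PERTURB_CACHE[order] = float(
            np.abs(np.real(sph_harm_y(order, m, tg, pg))).max())
    return raw / _PERTURB_CACHE[order]


def _lobulated_mask(spec: PhantomSpec) -> np.ndarray:
    """Voxel centers inside the star-convex solid r(theta, phi)."""
    center = spec.resolved_center()
    sp = np.asarray(spec.spacing_mm)
    rmax = spec.base_radius_mm * (1.0 + spec.lobulation_amp)
    extent = (np.asarray(spec.grid_shape) - 1) * sp
    for ax in range(3):
        if center[ax] - rmax < -sp[ax] / 2 or center[ax] + rmax > extent[ax] + sp[ax] / 2:
            raise ValueError(
                f"tumor (radius {rmax:.1f} mm) extends outside the grid on axis {ax}")
    coords = [np.arange(n) * s - c for n, s, c in zip(spec.grid_shape, sp, center)]
    dx, dy, dz = np.meshgrid(*coords, indexing="ij")
    r = np.sqrt(dx * dx + dy * dy + dz * dz)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.divide(dz, r, out=np.zeros_like(r), where=r > 0),
                                  -1.0, 1.0))
    phi = np.arctan2(dy, dx)
    radius = spec.base_radius_mm * (
        1.0 + spec.lobulation_amp * _perturbation(spec.lobulation_order, theta, phi))
    return r <= radius


def make_phantom_exam(spec: PhantomSpec,
                      timepoint: Timepoint = "T0",
                      patient_id: str = "phantom") -> Tuple[DceExam, TumorMask]:
    """Build one DCE exam (pre / early / late volumes) and its ground truth.

    Intensities: the pre-contrast volume is flat at 100; tumor-voxel PE
    and SER are drawn from the spec's distributions and the early / late
    volumes solved from them, so the exam segments back to the generating
    mask exactly when ``noise_sd == 0``. Additive Gaussian noise is then
    applied to all three volumes. Identical spec (incl. seed) gives
    bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    inside = _lobulated_mask(spec)
    shape = spec.grid_shape

    s_pre = np.full(shape, 100.0)
    pe = np.full(shape, spec.pe_background_mean)
    n_t = int(inside.sum())
    # truncated at +/- 3 sd: guarantees tumor/background PE separation
    # by construction whenever mean - 3 sd clears the threshold
    pe[inside] = np.clip(
        rng.normal(spec.pe_tumor_mean, spec.pe_tumor_sd, size=n_t),
        spec.pe_tumor_mean - 3 * spec.pe_tumor_sd,
        spec.pe_tumor_mean + 3 * spec.pe_tumor_sd)
    ser = np.full(shape, 0.5)  # persistent-enhancement background kinetics
    ser[inside] = np.clip(
        rng.normal(spec.ser_tumor_mean, spec.ser_tumor_sd, size=n_t), 0.2, None)
    s_early = s_pre * (1.0 + pe / 100.0)
    s_late = s_pre + (s_early - s_pre) / ser

    if spec.noise_sd > 0:
        s_pre = s_pre + rng.normal(0, spec.noise_sd, shape)
        s_early = s_early + rng.normal(0, spec.noise_sd, shape)
        s_late = s_late + rng.normal(0, spec.noise_sd, shape)

    if inside.any():
        idx = np.nonzero(inside)
        lo = [int(i.min()) for i in idx]
        hi = [int(i.max()) + 1 for i in idx]
    else:  # degenerate phantom: center the box anyway
        lo = [n // 2 for n in shape]
        hi = [n // 2 + 1 for n in shape]
    margin = 3
    voi = tuple((max(0, l - margin), min(n, h + margin))
                for l, h, n in zip(lo, hi, shape))
    exam = DceExam(patient_id=patient_id, timepoint=timepoint,
                   s_pre=s_pre, s_early=s_early, s_late=s_late,
                   spacing_mm=spec.spacing_mm, voi_box=voi)
    return exam, TumorMask(voxels=inside, spacing_mm=spec.spacing_mm, stage="raw")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-level generating distributions.

    The class-conditional treatment effect has two channels: a linear
    shrink factor s in (0, 1] (concentric scaling T0 -> T1) and an
    additive change in lobulation amplitude. Defaults give responders
    strong shrinkage plus roughening and poor responders (RCB-III) near
    shape preservation, reproducing the direction in which the
    surface-area-to-volume T1/T0 ratio separates the outcome groups.
    """

    n_patients: int = 100
    subtype_probs: Tuple[float, ...] = (0.39, 0.16, 0.09, 0.36)  # over SUBTYPES
    rcb_probs: Tuple[float, ...] = (0.346, 0.140, 0.359, 0.155)  # over RCB_CLASSES
    shrink_by_class: Dict[str, Tuple[float, float]] = field(default_factory=lambda: {
        "RCB-0": (0.45, 0.15), "RCB-I": (0.55, 0.15),
        "RCB-II": (0.70, 0.15), "RCB-III": (0.90, 0.08)})
    shape_change_by_class: Dict[str, Tuple[float, float]] = field(default_factory=lambda: {
        "RCB-0": (0.15, 0.05), "RCB-I": (0.10, 0.05),
        "RCB-II": (0.05, 0.05), "RCB-III": (0.00, 0.03)})
    degenerate_rate: float = 0.05
    age_mean: float = 48.8
    age_sd: float = 10.5
    # phantom geometry / kinetics shared by all patients
    spacing_mm: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    base_radius_mean_mm: float = 12.0
    base_radius_sd_mm: float = 3.0
    base_radius_range_mm: Tuple[float, float] = (6.0, 18.0)
    lobulation_amp_range: Tuple[float, float] = (0.05, 0.25)
    lobulation_order: int = 3
    pe_tumor_mean: float = 120.0
    pe_tumor_sd: float = 15.0
    pe_background_mean: float = 10.0
    ser_tumor_mean: float = 1.1
    ser_tumor_sd: float = 0.3
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        for name, p in (("subtype_probs", self.subtype_probs),
                        ("rcb_probs", self.rcb_probs)):
            if abs(sum(p) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1, got {sum(p)}")
        if not (0.0 <= self.degenerate_rate < 1.0):
            raise ValueError("degenerate_rate must lie in [0, 1)")
        for cls, (mu, _) in self.shrink_by_class.items():
            if not (0.0 < mu <= 1.0):
                raise ValueError(f"shrink mean for {cls} must lie in (0, 1]")


def _grid_for_radius(rmax_mm: float, spacing: Tuple[float, float, float]
                     ) -> Tuple[int, int, int]:
    """Smallest comfortable cubic grid containing a tumor of max radius rmax."""
    return tuple(int(np.ceil(2 * rmax_mm / s)) + 9 for s in spacing)


def draw_patient_attributes(config: CohortConfig, patient_index: int) -> dict:
    """Covariates, outcome class and latent tumor parameters for one patient.

    Seeded from (config.seed, patient_index) so each patient is
    reproducible independently of cohort iteration order.
    """
    rng = np.random.default_rng([config.seed, patient_index])
    subtype = SUBTYPES[rng.choice(4, p=np.asarray(config.subtype_probs))]
    rcb = RCB_CLASSES[rng.choice(4, p=np.asarray(config.rcb_probs))]
    race = RACE_LEVELS[rng.choice(len(RACE_LEVELS), p=np.asarray(RACE_PROBS))]
    meno = MENOPAUSE_LEVELS[rng.choice(len(MENOPAUSE_LEVELS),
                                       p=np.asarray(MENOPAUSE_PROBS))]
    age = float(np.clip(rng.normal(config.age_mean, config.age_sd), 21.0, 90.0))

    radius = float(np.clip(rng.normal(config.base_radius_mean_mm,
                                      config.base_radius_sd_mm),
                           *config.base_radius_range_mm))
    amp0 = float(rng.uniform(*config.lobulation_amp_range))
    mu_s, sd_s = config.shrink_by_class[rcb]
    s = float(np.clip(rng.normal(mu_s, sd_s), 0.05, 1.0))
    mu_d, sd_d = config.shape_change_by_class[rcb]
    amp1 = float(np.clip(amp0 + rng.normal(mu_d, sd_d), 0.0, 0.45))
    degenerate = bool(rng.random() < config.degenerate_rate)
    return {
        "patient_id": f"P{patient_index:04d}", "age": age, "race": race,
        "menopausal_status": meno, "hrher2_subtype": subtype, "rcb_class": rcb,
        "base_radius_mm": radius, "lobulation_amp_t0": amp0,
        "shrink_factor": s, "lobulation_amp_t1": amp1,
        "degenerate_t1": degenerate,
        "exam_seed": int(rng.integers(0, 2**31 - 1)),
    }


def simulate_patient(config: CohortConfig, patient_index: int):
    """One patient's T0/T1 exams, covariates, outcome and truth masks.

    The T1 tumor is the T0 tumor scaled by a class-drawn shrink factor
    with a class-drawn lobulation change; a degenerate draw collapses
    the T1 tumor below the shape-computable size instead of deleting it,
    so downstream missing-feature handling is exercised naturally.
    """
    attrs = draw_patient_attributes(config, patient_index)
    common = dict(spacing_mm=config.spacing_mm,
                  lobulation_order=config.lobulation_order,
                  pe_tumor_mean=config.pe_tumor_mean, pe_tumor_sd=config.pe_tumor_sd,
                  pe_background_mean=config.pe_background_mean,
                  ser_tumor_mean=config.ser_tumor_mean, ser_tumor_sd=config.ser_tumor_sd,
                  noise_sd=config.noise_sd)
    r0, a0 = attrs["base_radius_mm"], attrs["lobulation_amp_t0"]
    spec0 = PhantomSpec(grid_shape=_grid_for_radius(r0 * (1 + a0), config.spacing_mm),
                        base_radius_mm=r0, lobulation_amp=a0,
                        seed=attrs["exam_seed"], **common)
    if attrs["degenerate_t1"]:
        # collapse below the meshing floor: a ~1-voxel remnant
        r1, a1 = 0.9 * min(config.spacing_mm), 0.0
    else:
        r1, a1 = r0 * attrs["shrink_factor"], attrs["lobulation_amp_t1"]
    spec1 = PhantomSpec(grid_shape=_grid_for_radius(max(r1 * (1 + a1), 2.0),
                                                    config.spacing_mm),
                        base_radius_mm=r1, lobulation_amp=a1,
                        seed=attrs["exam_seed"] + 1, **common)
    exam0, truth0 = make_phantom_exam(spec0, "T0", attrs["patient_id"])
    exam1, truth1 = make_phantom_exam(spec1, "T1", attrs["patient_id"])
    covariates = {k: attrs[k] for k in
                  ("patient_id", "age", "race", "menopausal_status", "hrher2_subtype")}
    return exam0, exam1, covariates, attrs["rcb_class"], (truth0, truth1)


@dataclass
class CohortBundle:
    """All exams plus covariate and label tables for one simulated cohort."""
    exams: List[Tuple[DceExam, DceExam]]
    truth_masks: List[Tuple[TumorMask, TumorMask]]
    covariates: "object"   # pandas.DataFrame
    labels: "object"       # pandas.DataFrame
    config: CohortConfig


def simulate_cohort(config: CohortConfig) -> CohortBundle:
    """Simulate a full cohort; deterministic under ``config.seed``."""
    import pandas as pd

    if config.n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    exams, truths, covs, labels = [], [], [], []
    for i in range(config.n_patients):
        e0, e1, cov, rcb, tm = simulate_patient(config, i)
        exams.append((e0, e1))
        truths.append(tm)
        covs.append(cov)
        labels.append({"patient_id": cov["patient_id"], "rcb_class": rcb})
    return CohortBundle(exams=exams, truth_masks=truths,
                        covariates=pd.DataFrame(covs),
                        labels=pd.DataFrame(labels), config=config)
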