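"""Synthetic multi-fraction prostate courses for end-to-end testing.

The generator emulates the *shape* of a hypofractionated prostate cohort
treated with online adaptation on an MR-linac: nine patients, five fractions
of 36.25 Gy total prescription, a daily anatomy (online planning), a
verification anatomy (just before delivery), one online plan per fraction
conformal to that day's PTV, an offline reference plan, and optionally one
corrupted (excluded) fraction per cohort.

What is emulated
----------------
* A pelvic phantom of rasterized ellipsoids: prostate (+ urethra inside),
  seminal vesicles posterior-superior, bladder superior-anterior, rectum as a
  posterior tube, bowel superior.  CTVs are unions of target organs, PTVs are
  anisotropic margin expansions (default 5 mm, 3 mm posterior — a documented
  package default, not a clinical protocol value).
* Interfraction motion: a global rigid translation (couch/patient) shared by
  all organs, plus per-organ translations relative to the prostate for
  bladder, rectum and bowel (filling-driven) and a smaller one for the
  seminal vesicles (deformation).  Relative displacements have two parts: a
  day-to-day independent component and a *systematic random walk* across
  fractions, so anatomy drifts progressively away from the reference — the
  reason recently generated plans outperform the offline reference plan.
  The global component is what a prostate-anchored registration removes; the
  relative components are what make old plans fail.
* Intrafraction drift: a small translation (optionally biased) applied to
  every organ between daily and verification anatomy.
* Organ-filling jitter: per-fraction isotropic radius scaling of bladder and
  rectum.
* Progressive prostate swelling for designated patients: volume grows by a
  fixed factor per fraction (isotropic radius scaling about the prostate
  center), reproducing the patient whose target outgrew every stored plan.

The dose surrogate is geometric, not physical: prescription inside the PTV
with a smooth interior boost (SBRT-like hotspot, up to ``1 + hotspot_boost``
times prescription deep inside, so the CTV exceeds the 40 Gy coverage goal),
and Gaussian falloff with distance outside the PTV surface.  Every quantity
the analysis consumes is a dose-volume statistic of a static 3D dose field,
so no beam or heterogeneity modelling is required.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .ccpb import FractionRecord, check_verif_coverage
from .criteria import PlanEvaluation, default_criteria_a, evaluate_plan
from .dpr import CourseRecord, PlanRecord
from .geometry import (
    Grid,
    Mask,
    StructureSet,
    expand_margin,
    rasterize_ellipsoid,
)
from .metrics import DoseGrid, compute_dose_statistics

__all__ = [
    "OrganSpec",
    "CohortConfig",
    "ReferencePatient",
    "FractionGroundTruth",
    "SyntheticCourse",
    "make_reference_patient",
    "make_plan_dose",
    "sample_fraction",
    "simulate_cohort",
    "check_reference_calibration",
]


@dataclass
class OrganSpec:
    """Analytic ellipsoid parameters (mm) for one organ."""

    center: tuple[float, float, float]
    radii: tuple[float, float, float]


#: Base pelvic geometry (mm), before per-patient variation.  Axes:
#: x left-right, y posterior(-)/anterior(+), z inferior(-)/superior(+).
DEFAULT_ORGANS: Mapping[str, OrganSpec] = {
    "prostate": OrganSpec((0.0, 0.0, 0.0), (20.0, 18.0, 20.0)),
    "sv": OrganSpec((0.0, -10.0, 28.0), (22.0, 8.0, 9.0)),
    "bladder": OrganSpec((0.0, 28.0, 38.0), (32.0, 28.0, 26.0)),
    "rectum": OrganSpec((0.0, -32.0, -5.0), (10.0, 10.0, 40.0)),
    "bowel": OrganSpec((0.0, 8.0, 58.0), (30.0, 24.0, 12.0)),
    "urethra": OrganSpec((0.0, 0.0, 0.0), (3.5, 3.5, 19.0)),
}

_OAR_NAMES = ("bladder", "rectum", "bowel")
_PHYS_EXTENT = ((-50.0, 50.0), (-50.0, 68.0), (-50.0, 78.0))


@dataclass
class CohortConfig:
    """Study-design constants and scenario parameters for one cohort.

    Defaults mirror the study layout: nine patients, five fractions,
    36.25 Gy prescription, one corrupted fraction (patient index 4,
    fraction 5), and a designated swelling patient (index 2).  Motion
    magnitudes are scenario parameters of the generator, not estimates of
    any clinical population.
    """

    n_patients: int = 9
    n_fractions: int = 5
    prescription: float = 36.25
    spacing: float = 2.5  # mm, isotropic
    organs: Mapping[str, OrganSpec] = field(
        default_factory=lambda: copy.deepcopy(dict(DEFAULT_ORGANS))
    )
    ptv_margins: tuple[float, ...] = (5.0, 5.0, 3.0, 5.0, 5.0, 5.0)  # x-,x+,y-,y+,z-,z+
    interfraction_sd: float = 3.0  # mm per axis, global rigid shift (i.i.d.)
    organ_motion_sd: float = 3.0  # mm per axis, per-OAR day-to-day relative shift
    organ_walk_sd: float = 2.0  # mm per axis per fraction, per-OAR systematic drift
    sv_motion_sd: float = 2.5  # mm per axis, seminal-vesicle day-to-day shift
    sv_walk_sd: float = 2.0  # mm per axis per fraction, seminal-vesicle drift
    intrafraction_sd: float = 1.5  # mm per axis, daily -> verification drift
    intrafraction_bias: tuple[float, float, float] = (0.0, 0.0, 0.0)
    filling_jitter_sd: float = 0.10  # fractional radius SD, bladder & rectum
    patient_radii_sd: float = 0.04  # per-patient anatomical variation
    patient_center_sd: float = 2.0  # mm, per-patient OAR position variation
    swelling_rates: Mapping[int, float] = field(default_factory=lambda: {2: 0.5})
    penumbra_sigma: float = 4.0  # mm, dose falloff outside the PTV
    dose_flash_mm: float = 1.0  # mm, prescription isodose slack beyond the PTV
    hotspot_boost: float = 0.2  # peak interior dose excess (fraction of Rx)
    hotspot_sigma: float = 1.5  # mm, interior boost ramp
    corrupted: Sequence[tuple[int, int]] = ((4, 5),)  # (patient index, fraction)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_fractions < 1:
            raise ValueError("cohort needs at least one patient and one fraction")
        if self.prescription <= 0:
            raise ValueError("prescription must be positive")
        if min(
            self.interfraction_sd,
            self.organ_motion_sd,
            self.organ_walk_sd,
            self.sv_motion_sd,
            self.sv_walk_sd,
            self.intrafraction_sd,
            self.filling_jitter_sd,
        ) < 0:
            raise ValueError("motion and jitter SDs must be non-negative")
        if any(r < 0 for r in self.swelling_rates.values()):
            raise ValueError("swelling rates must be non-negative")
        for name, spec in self.organs.items():
            if min(spec.radii) <= 0:
                raise ValueError(f"organ {name!r} has a non-positive radius")

    def grid(self, frame_id: str = "world") -> Grid:
        shape = tuple(
            int(np.floor((hi - lo) / self.spacing)) + 1 for lo, hi in _PHYS_EXTENT
        )
        origin = tuple(lo for lo, _ in _PHYS_EXTENT)
        return Grid(shape=shape, spacing=(self.spacing,) * 3, origin=origin, frame_id=frame_id)

    def scaled_motion(self, scale: float) -> "CohortConfig":
        """A copy with every interfraction motion SD multiplied by ``scale``
        (global shift, per-organ day-to-day and systematic components).
        Intrafraction drift is left untouched."""
        return replace(
            self,
            interfraction_sd=self.interfraction_sd * scale,
            organ_motion_sd=self.organ_motion_sd * scale,
            organ_walk_sd=self.organ_walk_sd * scale,
            sv_motion_sd=self.sv_motion_sd * scale,
            sv_walk_sd=self.sv_walk_sd * scale,
        )

    @classmethod
    def zero_motion(cls, **overrides) -> "CohortConfig":
        """All motion, drift, jitter and swelling switched off."""
        base = dict(
            interfraction_sd=0.0,
            organ_motion_sd=0.0,
            organ_walk_sd=0.0,
            sv_motion_sd=0.0,
            sv_walk_sd=0.0,
            intrafraction_sd=0.0,
            intrafraction_bias=(0.0, 0.0, 0.0),
            filling_jitter_sd=0.0,
            swelling_rates={},
            corrupted=(),
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class ReferencePatient:
    patient_index: int
    organs: dict[str, OrganSpec]
    anatomy: StructureSet
    ct_ref: PlanRecord
    swelling_rate: float = 0.0


@dataclass
class FractionGroundTruth:
    """The sampled motion state that produced one fraction's anatomies.

    ``organ_shifts`` are the total relative displacements (systematic walk +
    day-to-day component); ``systematic`` is the walk state entering the next
    fraction."""

    global_shift: np.ndarray
    organ_shifts: dict[str, np.ndarray]
    systematic: dict[str, np.ndarray]
    drift: np.ndarray
    radius_factors: dict[str, float]
    swelling_scale: float


@dataclass
class SyntheticCourse:
    course: CourseRecord
    reference: ReferencePatient
    ground_truth: dict[int, FractionGroundTruth]


def _build_anatomy(
    organs: Mapping[str, OrganSpec],
    grid: Grid,
    margins: Sequence[float],
) -> StructureSet:
    """Rasterize organs and derive CTVs/PTVs on a grid."""
    masks = {
        name: rasterize_ellipsoid(spec.center, spec.radii, grid)
        for name, spec in organs.items()
    }
    masks["ctv_psv"] = Mask(grid, masks["prostate"].voxels | masks["sv"].voxels)
    masks["ctv_sv"] = Mask(grid, masks["sv"].voxels.copy())
    masks["ptv_psv"] = expand_margin(masks["ctv_psv"], margins)
    masks["ptv_sv"] = expand_margin(masks["ctv_sv"], margins)
    return StructureSet(structures=masks, frame_id=grid.frame_id)


def make_plan_dose(anatomy: StructureSet, config: CohortConfig) -> DoseGrid:
    """Analytic conformal dose for a planning anatomy.

    ``d(x) = Rx * (1 + b * (1 - exp(-max(din - s/2, 0)^2 / (2*sigma_in^2))))``
    inside the PTV (``din`` = distance to the PTV surface, ``s`` = voxel
    pitch, so PTV surface voxels sit at prescription and deep voxels at up to
    ``(1+b) * Rx``) and ``d(x) = Rx * exp(-max(dout - flash, 0)^2 /
    (2*penumbra_sigma^2))`` outside: the prescription isodose keeps a small
    slack (``dose_flash_mm``) beyond the PTV, as a robustly optimized plan's
    does, then falls off as a Gaussian.  Dose is non-increasing along any ray
    leaving the PTV.
    """
    if "ptv_psv" not in anatomy:
        raise ValueError("planning anatomy lacks a PTV (ptv_psv)")
    ptv = anatomy["ptv_psv"]
    if ptv.is_empty:
        raise ValueError("planning PTV is empty")
    spacing = anatomy.grid.spacing
    rx = config.prescription
    dist_out = ndimage.distance_transform_edt(~ptv.voxels, sampling=spacing)
    dist_in = ndimage.distance_transform_edt(ptv.voxels, sampling=spacing)
    # prescription isodose carries a little slack beyond the PTV, as a robustly
    # optimized plan's does; falloff starts at the flash distance
    dist_out = np.maximum(dist_out - config.dose_flash_mm, 0.0)
    dose = rx * np.exp(-(dist_out**2) / (2.0 * config.penumbra_sigma**2))
    din = np.maximum(dist_in - np.mean(spacing) / 2.0, 0.0)
    boost = 1.0 + config.hotspot_boost * (
        1.0 - np.exp(-(din**2) / (2.0 * config.hotspot_sigma**2))
    )
    dose = np.where(ptv.voxels, rx * boost, dose)
    return DoseGrid(anatomy.grid, dose)


def make_reference_patient(
    config: CohortConfig, patient_index: int, rng: np.random.Generator
) -> ReferencePatient:
    """Reference (planning-CT) anatomy and offline reference plan.

    Per-patient anatomical variation: small random radius scaling for every
    organ and position jitter for the OARs, so patients differ while the
    target stays centred in the grid.
    """
    grid = config.grid()
    organs: dict[str, OrganSpec] = {}
    for name, spec in config.organs.items():
        factors = 1.0 + np.clip(
            rng.normal(0.0, config.patient_radii_sd, size=3), -0.15, 0.15
        )
        radii = tuple(np.asarray(spec.radii) * factors)
        center = np.asarray(spec.center, dtype=float)
        if name in _OAR_NAMES:
            center = center + rng.normal(0.0, config.patient_center_sd, size=3)
        organs[name] = OrganSpec(tuple(center), tuple(radii))
    anatomy = _build_anatomy(organs, grid, config.ptv_margins)
    dose = make_plan_dose(anatomy, config)
    ct_ref = PlanRecord(
        plan_id="DPR_0", dose=dose, planning_anatomy=anatomy, source_fraction=0
    )
    return ReferencePatient(
        patient_index=patient_index,
        organs=organs,
        anatomy=anatomy,
        ct_ref=ct_ref,
        swelling_rate=dict(config.swelling_rates).get(patient_index, 0.0),
    )


def check_reference_calibration(reference: ReferencePatient) -> PlanEvaluation:
    """Generator self-check: the reference plan, evaluated on its own anatomy,
    must satisfy the clinical goals; otherwise the configured geometry makes
    the constraints unsatisfiable.  Raises with the failing metrics."""
    table_a = default_criteria_a()
    stats = compute_dose_statistics(
        reference.ct_ref.dose, reference.anatomy, table_a.metrics,
        plan_id="DPR_0", anatomy_id="reference",
    )
    ev = evaluate_plan(stats, table_a)
    if not ev.acceptable:
        failing = [
            f"{g.metric.label()}={g.value:.2f} ({g.grade.name})"
            for g in ev.grades
            if g.grade.name in ("UNACCEPTABLE", "MARGINAL")
        ]
        raise ValueError(
            "configured organ geometry makes the clinical goals unsatisfiable "
            f"for the reference plan: {', '.join(failing)}"
        )
    return ev


def _swelling_scale(rate: float, fraction_index: int) -> float:
    # volume factor (1+rate)^k  ->  radius factor (1+rate)^(k/3)
    return float((1.0 + rate) ** (fraction_index / 3.0))


def _ptv_inside_grid(anatomy: StructureSet) -> bool:
    """Reject samples whose PTV touches the grid boundary."""
    v = anatomy["ptv_psv"].voxels
    return not (
        v[0].any() or v[-1].any()
        or v[:, 0].any() or v[:, -1].any()
        or v[:, :, 0].any() or v[:, :, -1].any()
    )


def sample_fraction(
    reference: ReferencePatient,
    config: CohortConfig,
    fraction_index: int,
    rng: np.random.Generator,
    systematic: dict[str, np.ndarray] | None = None,
    max_rejections: int = 100,
) -> tuple[FractionRecord, PlanRecord, FractionGroundTruth]:
    """Sample one fraction's daily/verification anatomy and its online plan.

    Draws the global interfraction shift, advances each organ's systematic
    random walk and adds its day-to-day relative shift, draws filling jitter
    and intrafraction drift; applies the patient's swelling scale;
    re-rasterizes both anatomies analytically (so the sampled transforms
    reproduce them exactly); optimizes the online plan to the daily PTV; and
    classifies the workflow by the verification coverage check.  Samples that
    push the PTV off the grid are rejected and redrawn (bounded).

    ``systematic`` is the walk state from the previous fraction (organ name
    to cumulative relative displacement); ``None`` means no drift yet.  The
    advanced state is returned in the ground truth for the next call."""
    grid = reference.anatomy.grid
    scale = _swelling_scale(reference.swelling_rate, fraction_index)
    if systematic is None:
        systematic = {name: np.zeros(3) for name in (*_OAR_NAMES, "sv")}
    walk = {
        name: systematic[name]
        + rng.normal(
            0.0,
            config.sv_walk_sd if name == "sv" else config.organ_walk_sd,
            size=3,
        )
        for name in (*_OAR_NAMES, "sv")
    }
    for _ in range(max_rejections):
        global_shift = rng.normal(0.0, config.interfraction_sd, size=3)
        organ_shifts = {
            name: walk[name] + rng.normal(0.0, config.organ_motion_sd, size=3)
            for name in _OAR_NAMES
        }
        organ_shifts["sv"] = walk["sv"] + rng.normal(0.0, config.sv_motion_sd, size=3)
        radius_factors = {
            name: float(
                np.clip(1.0 + rng.normal(0.0, config.filling_jitter_sd), 0.5, 1.6)
            )
            for name in ("bladder", "rectum")
        }
        drift = rng.normal(0.0, config.intrafraction_sd, size=3) + np.asarray(
            config.intrafraction_bias, dtype=float
        )
        daily_organs: dict[str, OrganSpec] = {}
        for name, spec in reference.organs.items():
            center = np.asarray(spec.center) + global_shift + organ_shifts.get(
                name, np.zeros(3)
            )
            radii = np.asarray(spec.radii) * radius_factors.get(name, 1.0)
            if name in ("prostate", "urethra"):
                radii = radii * scale
            daily_organs[name] = OrganSpec(tuple(center), tuple(radii))
        try:
            daily = _build_anatomy(daily_organs, grid, config.ptv_margins)
            verif_organs = {
                name: OrganSpec(tuple(np.asarray(s.center) + drift), s.radii)
                for name, s in daily_organs.items()
            }
            verif = _build_anatomy(verif_organs, grid, config.ptv_margins)
        except ValueError:
            continue  # an organ left the grid entirely; redraw
        if not (_ptv_inside_grid(daily) and _ptv_inside_grid(verif)):
            continue
        plan_dose = make_plan_dose(daily, config)
        workflow = (
            "ATS"
            if check_verif_coverage(
                plan_dose, verif, threshold_gy=config.prescription
            )
            else "ATP_of_ATS"
        )
        fraction = FractionRecord(
            index=fraction_index,
            daily=daily,
            verif=verif,
            approved_plan_id=f"DPR_{fraction_index}",
            workflow=workflow,
        )
        plan = PlanRecord(
            plan_id=f"DPR_{fraction_index}",
            dose=plan_dose,
            planning_anatomy=daily,
            source_fraction=fraction_index,
        )
        truth = FractionGroundTruth(
            global_shift=global_shift,
            organ_shifts=organ_shifts,
            systematic=walk,
            drift=drift,
            radius_factors=radius_factors,
            swelling_scale=scale,
        )
        return fraction, plan, truth
    raise RuntimeError(
        f"could not sample fraction {fraction_index} inside the grid after "
        f"{max_rejections} rejections; reduce motion SDs or enlarge the grid"
    )


def simulate_cohort(
    config: CohortConfig, check_calibration: bool = False
) -> list[SyntheticCourse]:
    """Generate the full cohort (deterministic for a fixed config/seed).

    Corrupted fractions are flagged excluded and contribute neither an
    assessment nor a repository plan for later fractions."""
    corrupted = set((int(p), int(f)) for p, f in config.corrupted)
    courses: list[SyntheticCourse] = []
    for pi in range(config.n_patients):
        rng = np.random.default_rng([int(config.seed) % (2**31), pi])
        reference = make_reference_patient(config, pi, rng)
        if check_calibration:
            check_reference_calibration(reference)
        fractions: list[FractionRecord] = []
        plans: list[PlanRecord] = [reference.ct_ref]
        truths: dict[int, FractionGroundTruth] = {}
        systematic = None
        for k in range(1, config.n_fractions + 1):
            fraction, plan, truth = sample_fraction(
                reference, config, k, rng, systematic=systematic
            )
            truths[k] = truth
            systematic = truth.systematic
            if (pi, k) in corrupted:
                fraction.excluded = True
                fractions.append(fraction)
                continue  # corrupted: no usable plan enters the repository
            fractions.append(fraction)
            plans.append(plan)
        course = CourseRecord(
            patient_id=f"P{pi + 1}", fractions=fractions, plans=plans
        )
        courses.append(SyntheticCourse(course=course, reference=reference, ground_truth=truths))
    return courses
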