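"""Current Clinical Practice Benchmark (CCPB).

The benchmark asks: what dose statistics did the *approved* online plan
actually deliver, judged on the verification image (the anatomy closest in
time to delivery)?  Verification contours are rigidly copied onto the
approved plan's dose distribution — deliberately without motion compensation,
because the benchmark is meant to expose intrafraction motion.  For fractions
where the verification coverage check failed online, a virtual couch shift
(adapt-to-position) is applied to the dose first, as it was clinically.

The virtual couch shift here is a surrogate for segment-aperture morphing in
a commercial optimizer: the dose cloud is rigidly translated so its high-dose
region re-centers on the verification anchor structure, and no dose is
recomputed.  No claim of dosimetric equivalence to any specific treatment
planning system is made.

Pooled CCPB distributions over all assessable fractions of a cohort feed the
empirical derivation of Criteria B (see :func:`dprfeas.criteria.derive_criteria_b`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .criteria import CriteriaTable
from .geometry import Mask, RigidTransform, StructureSet
from .metrics import (
    DoseGrid,
    DoseStatistics,
    MetricSpec,
    compute_dose_statistics,
    v_dose,
)

__all__ = [
    "FractionRecord",
    "CCPBPool",
    "check_verif_coverage",
    "virtual_couch_shift",
    "compute_ccpb_for_fraction",
    "pool_ccpb",
    "daily_vs_verif_report",
]

#: Default online coverage check: PTV(prostate+SV) V_36.25Gy >= 90 %.
DEFAULT_COVERAGE_STRUCTURE = "ptv_psv"
DEFAULT_COVERAGE_DOSE_GY = 36.25
DEFAULT_COVERAGE_MIN_PCT = 90.0


@dataclass
class FractionRecord:
    """Bookkeeping for one delivered fraction of a course."""

    index: int  # 1-based fraction number
    daily: StructureSet  # anatomy at online planning time
    verif: StructureSet  # anatomy just before delivery
    approved_plan_id: str = ""
    workflow: str = "ATS"  # "ATS" or "ATP_of_ATS"
    couch_shift: RigidTransform | None = None
    excluded: bool = False  # corrupted data; carries no assessments

    def __post_init__(self) -> None:
        if self.workflow not in ("ATS", "ATP_of_ATS"):
            raise ValueError(f"unknown workflow {self.workflow!r}")
        if self.index < 1:
            raise ValueError("fraction index is 1-based")


@dataclass
class CCPBPool:
    """Per-metric benchmark value lists pooled over fractions and patients."""

    values: dict[MetricSpec, np.ndarray]
    n_fractions: int

    def quartiles(self, spec: MetricSpec) -> tuple[float, float]:
        v = self.values[spec]
        return float(np.percentile(v, 25)), float(np.percentile(v, 75))

    def relevant_quartile(self, spec: MetricSpec) -> float:
        """P25 for targets, P75 for OARs — the quartile Criteria B inspects."""
        p25, p75 = self.quartiles(spec)
        return p25 if spec.is_target else p75

    def flags(self, table_a: CriteriaTable) -> dict[MetricSpec, bool]:
        """Metrics whose relevant quartile violates the Criteria A bound."""
        out = {}
        for row in table_a.rows:
            q = self.relevant_quartile(row.metric)
            if row.metric.is_target:
                out[row.metric] = q < row.mandatory
            else:
                out[row.metric] = q > row.mandatory
        return out

    def to_frame(self, table_a: CriteriaTable | None = None) -> pd.DataFrame:
        flags = self.flags(table_a) if table_a is not None else None
        rows = []
        for spec, v in self.values.items():
            p25, p75 = self.quartiles(spec)
            row = {
                "metric": spec.label(),
                "n": int(v.size),
                "p25": p25,
                "median": float(np.median(v)),
                "p75": p75,
                "relevant_quartile": self.relevant_quartile(spec),
            }
            if flags is not None:
                row["violates_criteria_a"] = bool(flags[spec])
            rows.append(row)
        return pd.DataFrame(rows)


def check_verif_coverage(
    plan_dose: DoseGrid,
    verif: StructureSet,
    structure: str = DEFAULT_COVERAGE_STRUCTURE,
    threshold_gy: float = DEFAULT_COVERAGE_DOSE_GY,
    min_pct: float = DEFAULT_COVERAGE_MIN_PCT,
) -> bool:
    """Online verification gate: does the plan still cover the target?

    True iff the configured coverage metric (default PTV V_36.25Gy, relative)
    meets ``min_pct`` on the verification anatomy.
    """
    if structure not in verif:
        raise ValueError(f"coverage structure {structure!r} missing from verification set")
    cov = v_dose(plan_dose, verif[structure], threshold_gy, mode="rel")
    return cov >= min_pct


def _high_dose_center(dose: DoseGrid, frac_of_max: float = 0.9) -> np.ndarray:
    """Physical centroid of the high-dose region (proxy for the planned PTV)."""
    hot = dose.values >= frac_of_max * dose.max_dose
    if not hot.any():
        raise ValueError("dose grid has no high-dose region")
    idx_com = np.array(ndimage.center_of_mass(hot))
    return dose.grid.index_to_world(idx_com)


def virtual_couch_shift(
    plan_dose: DoseGrid,
    verif: StructureSet,
    anchor: str = "prostate",
    planned_anchor: Mask | None = None,
) -> tuple[DoseGrid, RigidTransform]:
    """Adapt-to-position surrogate: translate the dose onto the moved anchor.

    The dose cloud is shifted by the anchor structure's displacement between
    planning and verification — ``planned_anchor`` is the anchor's mask on
    the planning anatomy (when omitted, the centroid of the >= 90 %-of-max
    dose region stands in for the planned anchor position, an adequate proxy
    for an anchor-centred conformal dose).  Dose values are trilinearly
    interpolated; the shift is returned alongside the shifted dose.  If the
    verification anatomy equals the planning anatomy the shift is zero.

    Raises
    ------
    ValueError
        If the anchor is missing/empty, or the shift would push the
        high-dose region outside the grid.
    """
    if anchor not in verif:
        raise ValueError(f"anchor structure {anchor!r} missing from verification set")
    if verif[anchor].is_empty:
        raise ValueError(f"anchor structure {anchor!r} is empty")
    if planned_anchor is not None:
        plan_center = planned_anchor.center_of_mass()
    else:
        plan_center = _high_dose_center(plan_dose)
    t = verif[anchor].center_of_mass() - plan_center
    grid = plan_dose.grid
    # the translated high-dose bounding box (half-maximum) must stay on the grid
    hot = np.argwhere(plan_dose.values >= 0.5 * plan_dose.max_dose)
    lo = np.asarray(grid.origin)
    hi = lo + (np.asarray(grid.shape) - 1) * np.asarray(grid.spacing)
    bb_lo = grid.index_to_world(hot.min(axis=0)) + t
    bb_hi = grid.index_to_world(hot.max(axis=0)) + t
    half = np.asarray(grid.spacing) / 2.0
    if ((bb_lo < lo - half) | (bb_hi > hi + half)).any():
        raise ValueError("virtual couch shift would move the high-dose region off the grid")
    shift_vox = t / np.asarray(grid.spacing)
    shifted = ndimage.shift(plan_dose.values, shift_vox, order=1, mode="constant", cval=0.0)
    transform = RigidTransform(t, np.eye(3), grid.frame_id, grid.frame_id)
    return DoseGrid(grid, shifted), transform


def compute_ccpb_for_fraction(
    fraction: FractionRecord,
    plan_dose: DoseGrid,
    specs: Iterable[MetricSpec],
    anchor: str = "prostate",
) -> DoseStatistics:
    """Benchmark statistics for one fraction's approved plan.

    Verification contours are rigidly copied (identity within the fraction's
    frame, nearest-neighbour resampling if lattices differ) onto the approved
    dose; for adapt-to-position fractions the virtual couch shift (anchored
    on the daily — i.e. planning — anatomy) is applied to the dose first and
    recorded on the fraction record.
    """
    if fraction.excluded:
        raise ValueError(
            f"fraction {fraction.index} is excluded (corrupted data); no benchmark"
        )
    dose = plan_dose
    if fraction.workflow == "ATP_of_ATS":
        planned_anchor = fraction.daily[anchor] if anchor in fraction.daily else None
        dose, shift = virtual_couch_shift(
            plan_dose, fraction.verif, anchor=anchor, planned_anchor=planned_anchor
        )
        if fraction.couch_shift is None:
            fraction.couch_shift = shift
    return compute_dose_statistics(
        dose,
        fraction.verif,
        specs,
        plan_id=fraction.approved_plan_id,
        anatomy_id=f"verif_{fraction.index}",
    )


def pool_ccpb(stats_list: Sequence[DoseStatistics]) -> CCPBPool:
    """Pool per-fraction benchmark statistics into per-metric value lists."""
    if not stats_list:
        raise ValueError("cannot pool an empty benchmark cohort")
    specs = list(stats_list[0].values.keys())
    values = {
        spec: np.array([st.get(spec) for st in stats_list], dtype=float)
        for spec in specs
    }
    return CCPBPool(values=values, n_fractions=len(stats_list))


def daily_vs_verif_report(
    daily_stats: Sequence[DoseStatistics],
    verif_stats: Sequence[DoseStatistics],
    table_a: CriteriaTable,
) -> pd.DataFrame:
    """Paired distributions of each metric on planning vs verification anatomy.

    One row per metric with quartile markers for both anatomies, the paired
    median shift, and a flag marking metrics whose relevant verification
    quartile crosses the clinical-goal bound.
    """
    if len(daily_stats) != len(verif_stats):
        raise ValueError("daily and verification statistics must be paired")
    pool_d = pool_ccpb(daily_stats)
    pool_v = pool_ccpb(verif_stats)
    flags = pool_v.flags(table_a)
    rows = []
    for row in table_a.rows:
        spec = row.metric
        vd = pool_d.values[spec]
        vv = pool_v.values[spec]
        d25, d75 = pool_d.quartiles(spec)
        v25, v75 = pool_v.quartiles(spec)
        rows.append(
            {
                "metric": spec.label(),
                "direction": spec.direction,
                "n_pairs": int(vd.size),
                "daily_p25": d25,
                "daily_median": float(np.median(vd)),
                "daily_p75": d75,
                "verif_p25": v25,
                "verif_median": float(np.median(vv)),
                "verif_p75": v75,
                "median_paired_diff": float(np.median(vv - vd)),
                "bound_a": row.mandatory,
                "quartile_violates_a": bool(flags[spec]),
            }
        )
    return pd.DataFrame(rows)
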