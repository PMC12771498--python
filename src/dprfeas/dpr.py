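"""Dynamic Plan Repository (DPR) assessment.

At fraction ``n`` of a course, the repository holds the offline reference
plan (``DPR_0``) plus every online plan generated at fractions ``1..n-1``.
The day's contours are rigidly propagated *backwards* onto each repository
plan (translation-only registration on an anchor structure, prostate by
default), the full dose-metric panel is evaluated on that plan's dose, and
acceptability is decided under Criteria A, B and C.  Propagating contours to
dose — rather than recomputing dose on the new image — is what makes the
assessment cheap enough to run for every repository plan at every fraction.

Aggregation follows the study design: per patient, the number and percentage
of assessable fractions with at least one acceptable repository plan per
criteria set; across patients, median/IQR (linear-interpolation quartiles)
and mean/SD (sample SD, n−1) of both counts and percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ccpb import FractionRecord
from .criteria import (
    CriteriaTable,
    MarginalBudget,
    PlanAcceptability,
    evaluate_criteria_c,
    evaluate_plan,
)
from .geometry import StructureSet, apply_rigid, estimate_registration
from .metrics import DoseGrid, DoseStatistics, MetricSpec, compute_dose_statistics

__all__ = [
    "PlanRecord",
    "CourseRecord",
    "CellResult",
    "FractionAssessment",
    "AssessmentMatrix",
    "PatientCounts",
    "CohortSummary",
    "build_repository",
    "propagate_and_score",
    "assess_course",
    "count_propagations",
    "summarize_cohort",
    "reference_only_summary",
    "acceptability_heatmap",
]

CT_REF_ID = "DPR_0"

#: Heatmap cell categories.
CELL_NOT_APPLICABLE = "not_applicable"
CELL_UNACCEPTABLE = "unacceptable"
CELL_ACCEPTABLE_A = "acceptable_A"
CELL_ACCEPTABLE_B = "acceptable_B"
CELL_ACCEPTABLE_C = "acceptable_C_exceptional"
CELL_EXCLUDED = "excluded"


@dataclass
class PlanRecord:
    """One candidate plan: its dose and the anatomy it was optimized for."""

    plan_id: str
    dose: DoseGrid
    planning_anatomy: StructureSet
    source_fraction: int  # 0 for the offline reference plan, else fraction k

    @property
    def frame_id(self) -> str:
        return self.planning_anatomy.frame_id


@dataclass
class CourseRecord:
    """Per-patient bookkeeping: fractions, plans, reference-plan identity."""

    patient_id: str
    fractions: list[FractionRecord]
    plans: list[PlanRecord]

    def __post_init__(self) -> None:
        ids = [p.plan_id for p in self.plans]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate plan ids in course {self.patient_id}: {ids}")
        if not any(p.source_fraction == 0 for p in self.plans):
            raise ValueError(f"course {self.patient_id} lacks the reference plan (DPR_0)")

    @property
    def n_fractions(self) -> int:
        return len(self.fractions)

    @property
    def ct_ref(self) -> PlanRecord:
        return next(p for p in self.plans if p.source_fraction == 0)

    def plan_for_fraction(self, k: int) -> PlanRecord | None:
        for p in self.plans:
            if p.source_fraction == k:
                return p
        return None

    def reference_plan_id(self, fraction_index: int) -> str:
        """PLAN_ref: the offline reference at fraction 1, the fraction-1
        online plan thereafter (falling back to the reference if fraction 1
        produced no plan)."""
        if fraction_index <= 1:
            return self.ct_ref.plan_id
        p1 = self.plan_for_fraction(1)
        return p1.plan_id if p1 is not None else self.ct_ref.plan_id


def build_repository(course: CourseRecord, fraction_index: int) -> list[PlanRecord]:
    """Plans available for reuse at a fraction: DPR_0 plus all earlier online
    plans, in course order.  Excluded fractions contributed no plan."""
    if not (1 <= fraction_index <= course.n_fractions):
        raise ValueError(
            f"fraction index {fraction_index} out of range 1..{course.n_fractions}"
        )
    return sorted(
        (p for p in course.plans if p.source_fraction < fraction_index),
        key=lambda p: p.source_fraction,
    )


def propagate_and_score(
    fraction: FractionRecord,
    plan: PlanRecord,
    specs: Iterable[MetricSpec],
    anchor: str = "prostate",
    register: bool = True,
) -> DoseStatistics:
    """Backward-propagate the day's contours onto a repository plan and score.

    The daily structure set is registered to the plan's frame (translation on
    the anchor centroid), every contour is rigidly resampled onto the plan's
    dose grid, and the full metric panel is evaluated on the plan's dose.
    With ``register=False`` contours are copied without motion compensation
    (useful for motion-sensitivity analyses).
    """
    if register:
        transform = estimate_registration(
            fraction.daily, plan.planning_anatomy, anchor=anchor
        )
    else:
        from .geometry import RigidTransform

        if fraction.daily.frame_id != plan.frame_id:
            raise ValueError("cannot copy contours across frames without registration")
        transform = RigidTransform.identity(plan.frame_id)
    moved = {
        name: apply_rigid(mask, transform, plan.dose.grid)
        for name, mask in fraction.daily.structures.items()
    }
    propagated = StructureSet(
        structures=moved,
        roles=dict(fraction.daily.roles),
        frame_id=plan.dose.grid.frame_id,
    )
    return compute_dose_statistics(
        plan.dose,
        propagated,
        specs,
        plan_id=plan.plan_id,
        anatomy_id=f"daily_{fraction.index}",
    )


@dataclass
class CellResult:
    """Assessment of one repository plan at one fraction.

    ``stats`` is ``None`` when the plan was unassessable at this fraction."""

    acceptability: PlanAcceptability
    stats: DoseStatistics | None

    @property
    def plan_id(self) -> str:
        return self.acceptability.plan_id


@dataclass
class FractionAssessment:
    fraction_index: int
    excluded: bool
    cells: list[CellResult] = field(default_factory=list)
    approved_acceptable_a: bool | None = None
    approved_acceptable_b: bool | None = None

    @property
    def any_acceptable_a(self) -> bool:
        return any(c.acceptability.acceptable_a for c in self.cells)

    @property
    def any_acceptable_b(self) -> bool:
        return any(c.acceptability.acceptable_b for c in self.cells)

    @property
    def any_acceptable_c(self) -> bool:
        return any(c.acceptability.acceptable_c for c in self.cells)

    def cell_for(self, plan_id: str) -> CellResult | None:
        for c in self.cells:
            if c.plan_id == plan_id:
                return c
        return None


@dataclass
class AssessmentMatrix:
    """Per-course fraction × repository-plan acceptability grid."""

    patient_id: str
    plan_ids: list[str]
    fractions: list[FractionAssessment]
    reference_plan_ids: dict[int, str] = field(default_factory=dict)

    @property
    def assessable(self) -> list[FractionAssessment]:
        return [f for f in self.fractions if not f.excluded]

    def counts(self) -> "PatientCounts":
        fa = self.assessable
        return PatientCounts(
            patient_id=self.patient_id,
            n_a=sum(f.any_acceptable_a for f in fa),
            n_b=sum(f.any_acceptable_b for f in fa),
            n_c=sum(f.any_acceptable_c for f in fa),
            total=len(fa),
        )

    def counts_for_plan(self, plan_id_of_fraction) -> "PatientCounts":
        """Counts restricted to a single candidate per fraction.

        ``plan_id_of_fraction`` maps a fraction index to the plan id to
        consider (e.g. always ``DPR_0``, or the per-fraction PLAN_ref)."""
        n = {"a": 0, "b": 0, "c": 0}
        total = 0
        for f in self.assessable:
            total += 1
            cell = f.cell_for(plan_id_of_fraction(f.fraction_index))
            if cell is None:
                continue
            acc = cell.acceptability
            n["a"] += acc.acceptable_a
            n["b"] += acc.acceptable_b
            n["c"] += acc.acceptable_c
        return PatientCounts(self.patient_id, n["a"], n["b"], n["c"], total)


def assess_course(
    course: CourseRecord,
    table_a: CriteriaTable,
    table_b: CriteriaTable,
    approved_stats: dict[int, DoseStatistics],
    specs: Sequence[MetricSpec] | None = None,
    anchor: str = "prostate",
    budget_mode: str = "delivered",
    eps: float = 1e-6,
) -> AssessmentMatrix:
    """Assess every repository plan at every assessable fraction of a course.

    ``approved_stats`` maps fraction index to that fraction's benchmark
    statistics (approved plan on verification anatomy); they anchor
    Criteria C and the delivered-sequence marginal budgets.

    ``budget_mode='delivered'`` (default) charges the once-per-course
    marginal budget along the actually delivered plan sequence, so candidate
    plans at fraction ``n`` see the budget state produced by fractions
    ``1..n-1``.  ``budget_mode='fresh'`` evaluates every fraction's
    candidates against an unused budget.
    """
    if budget_mode not in ("delivered", "fresh"):
        raise ValueError("budget_mode must be 'delivered' or 'fresh'")
    if specs is None:
        specs = table_a.metrics
    budget_a = MarginalBudget()
    budget_b = MarginalBudget()
    plan_ids = [p.plan_id for p in sorted(course.plans, key=lambda p: p.source_fraction)]
    fractions: list[FractionAssessment] = []
    for fraction in course.fractions:
        if fraction.excluded:
            fractions.append(
                FractionAssessment(fraction_index=fraction.index, excluded=True)
            )
            continue
        app = approved_stats[fraction.index]
        eval_a_app = evaluate_plan(app, table_a, budget_a)
        eval_b_app = evaluate_plan(app, table_b, budget_b)
        fa = FractionAssessment(
            fraction_index=fraction.index,
            excluded=False,
            approved_acceptable_a=eval_a_app.acceptable,
            approved_acceptable_b=eval_b_app.acceptable,
        )
        cand_budget_a = MarginalBudget() if budget_mode == "fresh" else budget_a
        cand_budget_b = MarginalBudget() if budget_mode == "fresh" else budget_b
        for plan in build_repository(course, fraction.index):
            try:
                stats = propagate_and_score(fraction, plan, specs, anchor=anchor)
            except ValueError as exc:
                # propagation failure (contour off the plan grid, empty mask):
                # the plan is unassessable and conservatively not acceptable
                fa.cells.append(
                    CellResult(
                        acceptability=PlanAcceptability(
                            plan_id=plan.plan_id,
                            fraction_index=fraction.index,
                            acceptable_a=False,
                            acceptable_b=False,
                            acceptable_c=False,
                            used_marginal=False,
                            unassessable=True,
                            error=str(exc),
                        ),
                        stats=None,
                    )
                )
                continue
            ev_a = evaluate_plan(stats, table_a, cand_budget_a)
            ev_b = evaluate_plan(stats, table_b, cand_budget_b)
            acc_c = evaluate_criteria_c(
                stats, app, table_b, ev_b.acceptable, eval_b_app.acceptable, eps=eps
            )
            fa.cells.append(
                CellResult(
                    acceptability=PlanAcceptability(
                        plan_id=plan.plan_id,
                        fraction_index=fraction.index,
                        acceptable_a=ev_a.acceptable,
                        acceptable_b=ev_b.acceptable,
                        acceptable_c=acc_c,
                        used_marginal=ev_a.used_marginal or ev_b.used_marginal,
                        grades_a=ev_a.grades,
                        grades_b=ev_b.grades,
                    ),
                    stats=stats,
                )
            )
        fractions.append(fa)
        # the delivered (approved) plan consumes the marginal budget
        if eval_a_app.used_marginal:
            budget_a.charge()
        if eval_b_app.used_marginal:
            budget_b.charge()
    return AssessmentMatrix(
        patient_id=course.patient_id,
        plan_ids=plan_ids,
        fractions=fractions,
        reference_plan_ids={
            f.index: course.reference_plan_id(f.index) for f in course.fractions
        },
    )


def count_propagations(cohort: Sequence[CourseRecord]) -> int:
    """Total backward structure-set propagations over a cohort.

    Each non-excluded fraction contributes one propagation per repository
    plan available at that fraction."""
    total = 0
    for course in cohort:
        for fraction in course.fractions:
            if fraction.excluded:
                continue
            total += len(build_repository(course, fraction.index))
    return total


def count_assessable_fractions(cohort: Sequence[CourseRecord]) -> int:
    return sum(
        1 for c in cohort for f in c.fractions if not f.excluded
    )


@dataclass(frozen=True)
class PatientCounts:
    """Per-patient acceptable-fraction counts under each criteria set."""

    patient_id: str
    n_a: int
    n_b: int
    n_c: int
    total: int

    def pct(self, which: str) -> float:
        n = {"a": self.n_a, "b": self.n_b, "c": self.n_c}[which]
        if self.total == 0:
            return float("nan")
        return 100.0 * n / self.total


@dataclass
class CohortSummary:
    """Cohort-level aggregation of per-patient counts and percentages."""

    per_patient: pd.DataFrame  # one row per patient
    cohort: pd.DataFrame  # one row per (criteria, quantity)

    def stat(self, criteria: str, quantity: str, statistic: str) -> float:
        sel = self.cohort[
            (self.cohort["criteria"] == criteria.upper())
            & (self.cohort["quantity"] == quantity)
        ]
        return float(sel.iloc[0][statistic])


def _agg(values: np.ndarray) -> dict[str, float]:
    v = np.asarray(values, dtype=float)
    out = {
        "median": float(np.median(v)),
        "iqr": float(np.percentile(v, 75) - np.percentile(v, 25)),
        "mean": float(np.mean(v)),
        "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
    }
    return out


def summarize_cohort(counts: Sequence[PatientCounts]) -> CohortSummary:
    """Median/IQR and mean/SD of counts and percentages across patients.

    Quartiles use linear interpolation between order statistics; SD is the
    sample standard deviation (n−1).  Display percentages are rounded to the
    nearest integer in reports; raw values are retained here.
    """
    if not counts:
        raise ValueError("cohort summary needs at least one patient")
    per_patient = pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "n_a": c.n_a,
                "pct_a": c.pct("a"),
                "n_b": c.n_b,
                "pct_b": c.pct("b"),
                "n_c": c.n_c,
                "pct_c": c.pct("c"),
                "total_fractions": c.total,
            }
            for c in counts
        ]
    )
    rows = []
    for crit in ("a", "b", "c"):
        ns = np.array([c.__getattribute__(f"n_{crit}") for c in counts], dtype=float)
        ps = np.array([c.pct(crit) for c in counts], dtype=float)
        rows.append({"criteria": crit.upper(), "quantity": "count", **_agg(ns)})
        rows.append({"criteria": crit.upper(), "quantity": "percent", **_agg(ps)})
    totals = np.array([c.total for c in counts], dtype=float)
    rows.append({"criteria": "-", "quantity": "fractions", **_agg(totals)})
    return CohortSummary(per_patient=per_patient, cohort=pd.DataFrame(rows))


def reference_only_summary(
    matrices: Sequence[AssessmentMatrix],
) -> dict[str, CohortSummary]:
    """Cohort summaries restricted to single reference candidates.

    ``'ct_ref'`` considers only the offline reference plan at every fraction;
    ``'plan_ref'`` considers the per-fraction reference (offline plan at
    fraction 1, the fraction-1 online plan thereafter)."""
    ct_counts = [m.counts_for_plan(lambda k: CT_REF_ID) for m in matrices]
    plan_counts = [
        m.counts_for_plan(lambda k, m=m: m.reference_plan_ids[k]) for m in matrices
    ]
    return {
        "ct_ref": summarize_cohort(ct_counts),
        "plan_ref": summarize_cohort(plan_counts),
    }


def acceptability_heatmap(matrix: AssessmentMatrix) -> pd.DataFrame:
    """Per-course grid (rows = repository plans, columns = fractions).

    Cells carry the best verdict for that plan at that fraction:
    ``acceptable_A`` ⊂ ``acceptable_B`` ⊂ ``acceptable_C_exceptional``,
    ``unacceptable``, ``not_applicable`` (plan did not exist yet) or
    ``excluded`` (corrupted fraction)."""
    cols = {}
    for fa in matrix.fractions:
        col = {}
        for pid in matrix.plan_ids:
            if fa.excluded:
                col[pid] = CELL_EXCLUDED
                continue
            cell = fa.cell_for(pid)
            if cell is None:
                col[pid] = CELL_NOT_APPLICABLE
            else:
                acc = cell.acceptability
                if acc.acceptable_a:
                    col[pid] = CELL_ACCEPTABLE_A
                elif acc.acceptable_b:
                    col[pid] = CELL_ACCEPTABLE_B
                elif acc.acceptable_c:
                    col[pid] = CELL_ACCEPTABLE_C
                else:
                    col[pid] = CELL_UNACCEPTABLE
        cols[f"Tx{fa.fraction_index}"] = col
    frame = pd.DataFrame(cols)
    frame.index.name = "plan_id"
    return frame
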