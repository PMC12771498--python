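"""Constraint grading and plan acceptability under Criteria A, B and C.

Three nested notions of acceptability are implemented for candidate plans:

* **Criteria A — clinical goals.**  Every OAR metric must grade
  mandatory-or-better; every target metric must grade mandatory-or-better,
  except that *marginal* target coverage may be accepted for at most one
  fraction per course (the marginal budget).
* **Criteria B — current-clinical-practice benchmark.**  The same rule
  against an empirically relaxed table: for each target metric the mandatory
  bound is the more permissive of the A bound and the 25th percentile of the
  benchmark pool; for each OAR metric, of the A bound and the 75th
  percentile.  By construction B is never stricter than A.
* **Criteria C — exceptional circumstances.**  B, extended: when the
  *approved* plan itself violates B on the verification anatomy, a candidate
  is acceptable if it is equivalent-or-better than the approved plan on every
  metric (within a small relative tolerance that absorbs float noise).

All bounds are inclusive: a value exactly at a bound satisfies it.  A row may
carry ``can_be_unacceptable=False`` (the urethra hot-volume row), in which
case failing every bound still grades mandatory and can never reject a plan.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .metrics import DoseStatistics, MetricSpec

__all__ = [
    "Grade",
    "ConstraintRow",
    "CriteriaTable",
    "StructureGrade",
    "MarginalBudget",
    "PlanEvaluation",
    "PlanAcceptability",
    "load_criteria_table",
    "save_criteria_table",
    "default_criteria_a",
    "default_criteria_b_study",
    "grade_metric",
    "evaluate_plan",
    "derive_criteria_b",
    "evaluate_criteria_c",
]


class Grade(enum.IntEnum):
    """Per-structure grade; larger is better."""

    UNACCEPTABLE = 0
    MARGINAL = 1
    MANDATORY = 2
    OPTIMAL = 3


@dataclass(frozen=True)
class ConstraintRow:
    """Graded bounds for one metric.

    Target rows compare with ``>=`` (coverage), OAR rows with ``<=``
    (sparing).  ``marginal`` is only meaningful for target metrics.
    """

    metric: MetricSpec
    mandatory: float
    optimal: float | None = None
    marginal: float | None = None
    can_be_unacceptable: bool = True

    def __post_init__(self) -> None:
        if self.metric.is_target:
            if self.optimal is not None and self.optimal < self.mandatory:
                raise ValueError(
                    f"{self.metric.label()}: target optimal bound must be >= mandatory"
                )
            if self.marginal is not None and self.marginal > self.mandatory:
                raise ValueError(
                    f"{self.metric.label()}: target marginal bound must be <= mandatory"
                )
        else:
            if self.marginal is not None:
                raise ValueError(
                    f"{self.metric.label()}: marginal bounds apply to target metrics only"
                )
            if self.optimal is not None and self.optimal > self.mandatory:
                raise ValueError(
                    f"{self.metric.label()}: OAR optimal bound must be <= mandatory"
                )


@dataclass
class CriteriaTable:
    """A labelled set of constraint rows, one per metric."""

    label: str
    rows: list[ConstraintRow]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("criteria table must contain at least one row")
        seen = set()
        for row in self.rows:
            if row.metric in seen:
                raise ValueError(f"duplicate metric {row.metric.label()} in criteria table")
            seen.add(row.metric)

    @property
    def metrics(self) -> list[MetricSpec]:
        return [r.metric for r in self.rows]

    def row_for(self, spec: MetricSpec) -> ConstraintRow:
        for row in self.rows:
            if row.metric == spec:
                return row
        raise KeyError(f"metric {spec.label()} not in criteria table {self.label}")


@dataclass(frozen=True)
class StructureGrade:
    metric: MetricSpec
    value: float
    grade: Grade


@dataclass
class MarginalBudget:
    """Once-per-course allowance for marginal target coverage."""

    capacity: int = 1
    used: int = 0

    @property
    def has_capacity(self) -> bool:
        return self.used < self.capacity

    def charge(self) -> None:
        if not self.has_capacity:
            raise RuntimeError("marginal budget already exhausted for this course")
        self.used += 1


@dataclass
class PlanEvaluation:
    """Outcome of grading one plan's statistics against one criteria table."""

    table_label: str
    acceptable: bool
    used_marginal: bool
    grades: list[StructureGrade]


@dataclass
class PlanAcceptability:
    """Combined A/B/C verdicts for one candidate plan at one fraction."""

    plan_id: str
    fraction_index: int
    acceptable_a: bool
    acceptable_b: bool
    acceptable_c: bool
    used_marginal: bool
    grades_a: list[StructureGrade] = field(default_factory=list)
    grades_b: list[StructureGrade] = field(default_factory=list)
    #: propagation failed (e.g. a contour left the plan's grid); the plan is
    #: conservatively not acceptable under any criteria
    unassessable: bool = False
    error: str = ""


# ---------------------------------------------------------------------------
# table I/O

def _row_from_dict(d: Mapping) -> ConstraintRow:
    spec = MetricSpec(
        structure=d["structure"],
        kind=d["metric_kind"],
        level=float(d["level"]),
        direction=d["direction"],
    )
    if d.get("mandatory") is None:
        raise ValueError(f"metric {spec.label()}: mandatory bound is required")
    return ConstraintRow(
        metric=spec,
        mandatory=float(d["mandatory"]),
        optimal=None if d.get("optimal") is None else float(d["optimal"]),
        marginal=None if d.get("marginal") is None else float(d["marginal"]),
        can_be_unacceptable=bool(d.get("can_be_unacceptable", True)),
    )


def _row_to_dict(row: ConstraintRow) -> dict:
    return {
        "structure": row.metric.structure,
        "metric_kind": row.metric.kind,
        "level": row.metric.level,
        "direction": row.metric.direction,
        "optimal": row.optimal,
        "mandatory": row.mandatory,
        "marginal": row.marginal,
        "can_be_unacceptable": row.can_be_unacceptable,
    }


def load_criteria_table(source) -> CriteriaTable:
    """Load and validate a criteria table from a JSON file path or dict."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            payload = json.load(fh)
    else:
        payload = source
    return CriteriaTable(
        label=payload["label"], rows=[_row_from_dict(r) for r in payload["rows"]]
    )


def save_criteria_table(table: CriteriaTable, path) -> None:
    payload = {"label": table.label, "rows": [_row_to_dict(r) for r in table.rows]}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def _load_packaged(name: str) -> CriteriaTable:
    with resources.files("dprfeas.data").joinpath(name).open() as fh:
        return load_criteria_table(json.load(fh))


def default_criteria_a() -> CriteriaTable:
    """The shipped clinical-goal table (Criteria A)."""
    return _load_packaged("criteria_a.json")


def default_criteria_b_study() -> CriteriaTable:
    """The shipped benchmark-relaxed table (Criteria B): PTV D98% and rectum
    V36Gy bounds relaxed to 32.38 Gy and 3.04 cm³ respectively."""
    return _load_packaged("criteria_b_study.json")


# ---------------------------------------------------------------------------
# grading

def _satisfies(value: float, bound: float, is_target: bool) -> bool:
    return value >= bound if is_target else value <= bound


def grade_metric(value: float, row: ConstraintRow) -> StructureGrade:
    """Best grade whose (inclusive) bound the value satisfies."""
    if not np.isfinite(value):
        raise ValueError(f"{row.metric.label()}: value must be finite, got {value}")
    t = row.metric.is_target
    if row.optimal is not None and _satisfies(value, row.optimal, t):
        g = Grade.OPTIMAL
    elif _satisfies(value, row.mandatory, t):
        g = Grade.MANDATORY
    elif row.marginal is not None and _satisfies(value, row.marginal, t):
        g = Grade.MARGINAL
    elif row.can_be_unacceptable:
        g = Grade.UNACCEPTABLE
    else:
        g = Grade.MANDATORY
    return StructureGrade(metric=row.metric, value=float(value), grade=g)


def evaluate_plan(
    stats: DoseStatistics,
    table: CriteriaTable,
    budget: MarginalBudget | int | None = None,
) -> PlanEvaluation:
    """Grade a full metric panel and decide acceptability under one table.

    A plan is acceptable iff every OAR metric grades mandatory-or-better and
    either (i) every target metric grades mandatory-or-better, or (ii) every
    target metric grades marginal-or-better *and* the marginal budget has
    capacity.  ``used_marginal`` records that path (ii) was needed; the caller
    charges the budget only when this plan is actually the fraction's selected
    plan.
    """
    if budget is None:
        budget = MarginalBudget()
    elif isinstance(budget, int):
        budget = MarginalBudget(used=budget)
    grades = [grade_metric(stats.get(row.metric), row) for row in table.rows]
    oars_ok = all(
        g.grade >= Grade.MANDATORY for g in grades if not g.metric.is_target
    )
    target_grades = [g.grade for g in grades if g.metric.is_target]
    targets_mandatory = all(g >= Grade.MANDATORY for g in target_grades)
    targets_marginal = all(g >= Grade.MARGINAL for g in target_grades)
    if targets_mandatory:
        acceptable, used_marginal = oars_ok, False
    elif targets_marginal and budget.has_capacity:
        acceptable, used_marginal = oars_ok, oars_ok
    else:
        acceptable, used_marginal = False, False
    return PlanEvaluation(
        table_label=table.label,
        acceptable=acceptable,
        used_marginal=used_marginal,
        grades=grades,
    )


# ---------------------------------------------------------------------------
# Criteria B derivation

def derive_criteria_b(
    pooled: Mapping[MetricSpec, Sequence[float]],
    table_a: CriteriaTable,
    min_pool: int = 4,
) -> tuple[CriteriaTable, dict[MetricSpec, tuple[float, float]]]:
    """Relax Criteria A using benchmark-pool quartiles.

    For every target metric the new mandatory bound is ``min(P25, A bound)``;
    for every OAR metric ``max(P75, A bound)`` — i.e. the more permissive of
    the pooled quartile and the clinical goal.  Percentiles use linear
    interpolation between order statistics.  Optimal bounds are copied; a
    target marginal bound is clamped down to the new mandatory bound if the
    relaxation crosses it.

    Returns the new table (label ``"B"``) and a map of changed metrics to
    ``(old bound, new bound)``.
    """
    new_rows: list[ConstraintRow] = []
    changed: dict[MetricSpec, tuple[float, float]] = {}
    for row in table_a.rows:
        values = np.asarray(pooled.get(row.metric, ()), dtype=float)
        if values.size == 0:
            raise ValueError(
                f"empty benchmark distribution for metric {row.metric.label()}"
            )
        if values.size < min_pool:
            raise ValueError(
                f"benchmark pool for {row.metric.label()} has {values.size} values; "
                f"at least {min_pool} required"
            )
        if row.metric.is_target:
            q = float(np.percentile(values, 25))
            new_bound = min(q, row.mandatory)
        else:
            q = float(np.percentile(values, 75))
            new_bound = max(q, row.mandatory)
        marginal = row.marginal
        if marginal is not None and marginal > new_bound:
            marginal = new_bound
        new_rows.append(
            ConstraintRow(
                metric=row.metric,
                mandatory=new_bound,
                optimal=row.optimal,
                marginal=marginal,
                can_be_unacceptable=row.can_be_unacceptable,
            )
        )
        if new_bound != row.mandatory:
            changed[row.metric] = (row.mandatory, new_bound)
    return CriteriaTable(label="B", rows=new_rows), changed


# ---------------------------------------------------------------------------
# Criteria C

def evaluate_criteria_c(
    dpr_stats: DoseStatistics,
    approved_stats: DoseStatistics,
    table_b: CriteriaTable,
    plan_b_acceptable: bool,
    approved_b_acceptable: bool,
    eps: float = 1e-6,
) -> bool:
    """Exceptional-circumstance acceptability.

    B-acceptable plans are C-acceptable.  Otherwise, only when the approved
    plan itself violates Criteria B (an exceptional circumstance) is the
    candidate accepted — and then only if it is equivalent or better than the
    approved plan on *every* metric (``>=`` for targets, ``<=`` for OARs,
    with relative tolerance ``eps``).
    """
    if plan_b_acceptable:
        return True
    if approved_b_acceptable:
        return False
    for row in table_b.rows:
        v_dpr = dpr_stats.get(row.metric)
        v_app = approved_stats.get(row.metric)
        tol = eps * max(1.0, abs(v_app))
        if row.metric.is_target:
            if v_dpr < v_app - tol:
                return False
        else:
            if v_dpr > v_app + tol:
                return False
    return True
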