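"""Pipeline orchestration: benchmark → Criteria B → assessment → summaries.

Stage order mirrors the analysis: (1) benchmark statistics for every
approved plan on its verification anatomy, (2) cohort pooling and the
empirical Criteria-B derivation, (3) repository assessment of every fraction
under Criteria A/B/C, (4) cohort and reference-only summaries plus
per-patient heatmaps.  Outputs are CSV/JSON in the output directory; any
stage failure removes the files written by this run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .ccpb import compute_ccpb_for_fraction, daily_vs_verif_report, pool_ccpb
from .criteria import (
    CriteriaTable,
    default_criteria_a,
    default_criteria_b_study,
    derive_criteria_b,
    load_criteria_table,
    save_criteria_table,
)
from .dpr import (
    AssessmentMatrix,
    CohortSummary,
    CourseRecord,
    acceptability_heatmap,
    assess_course,
    reference_only_summary,
    summarize_cohort,
)
from .io import read_manifest, write_csv
from .metrics import DoseStatistics, compute_dose_statistics, statistics_to_frame

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("dprfeas")


@dataclass
class PipelineConfig:
    """Configuration of one full analysis run."""

    manifest: Path
    out_dir: Path
    criteria_a: Path | None = None  # None -> shipped clinical-goal table
    criteria_b: str | Path = "derive"  # "derive", "study", or a JSON path
    anchor: str = "prostate"
    budget_mode: str = "delivered"
    eps: float = 1e-6

    def resolve_table_a(self) -> CriteriaTable:
        if self.criteria_a is None:
            return default_criteria_a()
        return load_criteria_table(self.criteria_a)

    def resolve_table_b(self, derived: CriteriaTable | None) -> CriteriaTable:
        if self.criteria_b == "derive":
            if derived is None:
                raise ValueError("criteria_b='derive' requires benchmark pooling")
            return derived
        if self.criteria_b == "study":
            return default_criteria_b_study()
        return load_criteria_table(self.criteria_b)


@dataclass
class PipelineResult:
    table_a: CriteriaTable
    table_b: CriteriaTable
    matrices: list[AssessmentMatrix]
    summary: CohortSummary
    reference_summaries: dict[str, CohortSummary]
    outputs: list[Path] = field(default_factory=list)


def compute_benchmark(
    courses: list[CourseRecord], specs, anchor: str = "prostate"
) -> tuple[dict[tuple[str, int], DoseStatistics], list[DoseStatistics], list[DoseStatistics]]:
    """Per-fraction benchmark (verification) and planning-anatomy statistics."""
    ccpb: dict[tuple[str, int], DoseStatistics] = {}
    daily_stats: list[DoseStatistics] = []
    verif_stats: list[DoseStatistics] = []
    for course in courses:
        for fraction in course.fractions:
            if fraction.excluded:
                continue
            plan = course.plan_for_fraction(fraction.index)
            if plan is None:
                raise ValueError(
                    f"{course.patient_id} fraction {fraction.index}: no approved plan"
                )
            daily = compute_dose_statistics(
                plan.dose,
                fraction.daily,
                specs,
                plan_id=plan.plan_id,
                anatomy_id=f"{course.patient_id}/daily_{fraction.index}",
            )
            stat = compute_ccpb_for_fraction(fraction, plan.dose, specs, anchor=anchor)
            stat.anatomy_id = f"{course.patient_id}/verif_{fraction.index}"
            ccpb[(course.patient_id, fraction.index)] = stat
            daily_stats.append(daily)
            verif_stats.append(stat)
    return ccpb, daily_stats, verif_stats


def summary_frame(summary: CohortSummary) -> pd.DataFrame:
    """Per-patient rows followed by cohort statistic rows (raw values)."""
    per = summary.per_patient.copy()
    stat_rows = []
    for stat in ("median", "iqr", "mean", "sd"):
        row = {"patient_id": stat}
        for crit in ("a", "b", "c"):
            cnt = summary.cohort[
                (summary.cohort["criteria"] == crit.upper())
                & (summary.cohort["quantity"] == "count")
            ].iloc[0]
            pct = summary.cohort[
                (summary.cohort["criteria"] == crit.upper())
                & (summary.cohort["quantity"] == "percent")
            ].iloc[0]
            row[f"n_{crit}"] = cnt[stat]
            row[f"pct_{crit}"] = pct[stat]
        tot = summary.cohort[summary.cohort["quantity"] == "fractions"].iloc[0]
        row["total_fractions"] = tot[stat]
        stat_rows.append(row)
    return pd.concat([per, pd.DataFrame(stat_rows)], ignore_index=True)


def format_cohort_table(summary: CohortSummary) -> str:
    """Human-readable cohort table: percentages to 0 decimals, counts to 2."""
    frame = summary_frame(summary)
    out = frame.copy()
    for col in out.columns:
        if col.startswith("pct_"):
            out[col] = out[col].map(lambda v: f"{v:.0f}")
        elif col.startswith("n_") or col == "total_fractions":
            out[col] = out[col].map(
                lambda v: f"{v:.2f}" if float(v) != int(float(v)) else f"{int(float(v))}"
            )
    return out.to_string(index=False)


def _assessments_frame(matrices: list[AssessmentMatrix]) -> pd.DataFrame:
    rows = []
    for m in matrices:
        for fa in m.fractions:
            if fa.excluded:
                rows.append(
                    {
                        "patient_id": m.patient_id,
                        "fraction": fa.fraction_index,
                        "plan_id": "",
                        "excluded": True,
                        "acceptable_a": False,
                        "acceptable_b": False,
                        "acceptable_c": False,
                        "used_marginal": False,
                        "approved_acceptable_a": False,
                        "approved_acceptable_b": False,
                    }
                )
                continue
            for cell in fa.cells:
                acc = cell.acceptability
                rows.append(
                    {
                        "patient_id": m.patient_id,
                        "fraction": fa.fraction_index,
                        "plan_id": acc.plan_id,
                        "excluded": False,
                        "acceptable_a": acc.acceptable_a,
                        "acceptable_b": acc.acceptable_b,
                        "acceptable_c": acc.acceptable_c,
                        "used_marginal": acc.used_marginal,
                        "approved_acceptable_a": fa.approved_acceptable_a,
                        "approved_acceptable_b": fa.approved_acceptable_b,
                    }
                )
    return pd.DataFrame(rows)


def _grades_frame(matrices: list[AssessmentMatrix]) -> pd.DataFrame:
    rows = []
    for m in matrices:
        for fa in m.fractions:
            for cell in fa.cells:
                ga = {g.metric: g for g in cell.acceptability.grades_a}
                gb = {g.metric: g for g in cell.acceptability.grades_b}
                for spec, g in ga.items():
                    rows.append(
                        {
                            "patient_id": m.patient_id,
                            "fraction": fa.fraction_index,
                            "plan_id": cell.plan_id,
                            "metric": spec.label(),
                            "value": g.value,
                            "grade_a": g.grade.name.lower(),
                            "grade_b": gb[spec].grade.name.lower(),
                        }
                    )
    return pd.DataFrame(rows)


def _reference_frame(ref_summaries: dict[str, CohortSummary]) -> pd.DataFrame:
    frames = []
    for subset, summary in ref_summaries.items():
        frame = summary_frame(summary)
        frame.insert(0, "subset", subset)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: PipelineConfig, courses: list[CourseRecord] | None = None) -> PipelineResult:
    """Execute all stages; write reports under ``config.out_dir``.

    ``courses`` may be passed directly to skip manifest reading (in-memory
    use); otherwise the manifest is loaded from ``config.manifest``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, frame: pd.DataFrame, index: bool = False) -> Path:
        fp = out / name
        write_csv(frame, fp, index=index)
        written.append(fp)
        return fp

    try:
        t0 = time.perf_counter()
        if courses is None:
            courses = read_manifest(config.manifest)
        table_a = config.resolve_table_a()
        specs = table_a.metrics
        log.info("loaded %d patients (%.1fs)", len(courses), time.perf_counter() - t0)

        t0 = time.perf_counter()
        ccpb_stats, daily_stats, verif_stats = compute_benchmark(
            courses, specs, anchor=config.anchor
        )
        emit("ccpb_stats.csv", statistics_to_frame(verif_stats))
        pool = pool_ccpb(verif_stats)
        emit("ccpb_pool.csv", pool.to_frame(table_a))
        emit("daily_vs_verif.csv", daily_vs_verif_report(daily_stats, verif_stats, table_a))
        log.info(
            "benchmark: %d fractions pooled (%.1fs)",
            pool.n_fractions,
            time.perf_counter() - t0,
        )

        derived = None
        if config.criteria_b == "derive":
            derived, changed = derive_criteria_b(pool.values, table_a)
            fp = out / "criteria_b_derived.json"
            save_criteria_table(derived, fp)
            written.append(fp)
            log.info(
                "criteria B: %d bound(s) relaxed: %s",
                len(changed),
                {k.label(): v for k, v in changed.items()},
            )
        table_b = config.resolve_table_b(derived)

        t0 = time.perf_counter()
        matrices = []
        for course in courses:
            approved = {
                idx: st for (pid, idx), st in ccpb_stats.items() if pid == course.patient_id
            }
            matrices.append(
                assess_course(
                    course,
                    table_a,
                    table_b,
                    approved,
                    specs=specs,
                    anchor=config.anchor,
                    budget_mode=config.budget_mode,
                    eps=config.eps,
                )
            )
        emit("assessments.csv", _assessments_frame(matrices))
        emit("grades.csv", _grades_frame(matrices))
        for m in matrices:
            emit(f"heatmap_{m.patient_id}.csv", acceptability_heatmap(m), index=True)
        log.info("assessed %d courses (%.1fs)", len(matrices), time.perf_counter() - t0)

        summary = summarize_cohort([m.counts() for m in matrices])
        emit("cohort_summary.csv", summary_frame(summary))
        ref_summaries = reference_only_summary(matrices)
        emit("reference_summary.csv", _reference_frame(ref_summaries))
        return PipelineResult(
            table_a=table_a,
            table_b=table_b,
            matrices=matrices,
            summary=summary,
            reference_summaries=ref_summaries,
            outputs=written,
        )
    except Exception:
        for fp in written:
            fp.unlink(missing_ok=True)
        raise
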