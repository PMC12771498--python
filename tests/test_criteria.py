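"""Criteria tables, grading, marginal budget, B derivation and Criteria C."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dprfeas.criteria import (
    ConstraintRow,
    CriteriaTable,
    Grade,
    MarginalBudget,
    default_criteria_a,
    default_criteria_b_study,
    derive_criteria_b,
    evaluate_criteria_c,
    evaluate_plan,
    grade_metric,
    load_criteria_table,
    save_criteria_table,
)
from dprfeas.metrics import DoseStatistics, MetricSpec


def spec_of(table, structure, kind, level):
    for row in table.rows:
        m = row.metric
        if m.structure == structure and m.kind == kind and m.level == level:
            return row
    raise KeyError((structure, kind, level))


def make_stats(table, grade="optimal"):
    """Statistics sitting exactly at a chosen bound of every row."""
    stats = DoseStatistics("p", "a")
    for row in table.rows:
        bound = {"optimal": row.optimal, "mandatory": row.mandatory, "marginal": row.marginal}[
            grade
        ]
        if bound is None:
            bound = row.mandatory
        stats.values[row.metric] = float(bound)
    return stats


class TestShippedTables:
    def test_clinical_goal_bounds(self):
        a = default_criteria_a()
        rectum = spec_of(a, "rectum", "v_dose_abs", 36.0)
        assert (rectum.optimal, rectum.mandatory) == (1.0, 2.0)
        d98 = spec_of(a, "ptv_psv", "d_percent", 98.0)
        assert (d98.optimal, d98.mandatory, d98.marginal) == (34.4, 33.71, None)
        ctv = spec_of(a, "ctv_psv", "v_dose_rel", 40.0)
        assert (ctv.optimal, ctv.mandatory, ctv.marginal) == (95.0, 90.0, 85.0)
        urethra = spec_of(a, "urethra", "v_dose_rel", 42.0)
        assert not urethra.can_be_unacceptable

    def test_benchmark_table_relaxations(self):
        b = default_criteria_b_study()
        assert spec_of(b, "rectum", "v_dose_abs", 36.0).mandatory == 3.04
        assert spec_of(b, "ptv_psv", "d_percent", 98.0).mandatory == 32.38
        # every other bound identical to the clinical goals
        a = default_criteria_a()
        for row_a, row_b in zip(a.rows, b.rows):
            if row_a.metric in (
                spec_of(a, "rectum", "v_dose_abs", 36.0).metric,
                spec_of(a, "ptv_psv", "d_percent", 98.0).metric,
            ):
                continue
            assert row_a.mandatory == row_b.mandatory

    def test_benchmark_never_stricter(self):
        a, b = default_criteria_a(), default_criteria_b_study()
        for row_a, row_b in zip(a.rows, b.rows):
            if row_a.metric.is_target:
                assert row_b.mandatory <= row_a.mandatory
            else:
                assert row_b.mandatory >= row_a.mandatory

    def test_roundtrip_through_json(self, tmp_path):
        a = default_criteria_a()
        fp = tmp_path / "a.json"
        save_criteria_table(a, fp)
        again = load_criteria_table(fp)
        assert again.rows == a.rows

    def test_empty_rows_rejected(self):
        with pytest.raises(ValueError, match="at least one row"):
            CriteriaTable(label="A", rows=[])

    def test_duplicate_metric_rejected(self):
        row = ConstraintRow(
            MetricSpec("rectum", "v_dose_abs", 36.0, "oar_sparing"), mandatory=2.0
        )
        with pytest.raises(ValueError, match="duplicate"):
            CriteriaTable(label="A", rows=[row, row])

    def test_target_marginal_above_mandatory_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            ConstraintRow(
                MetricSpec("ptv_psv", "v_dose_rel", 36.25, "target_coverage"),
                mandatory=90.0,
                marginal=95.0,
            )


class TestGradeMetric:
    def test_target_marginal_band(self):
        row = spec_of(default_criteria_a(), "ctv_psv", "v_dose_rel", 40.0)
        assert grade_metric(87.0, row).grade == Grade.MARGINAL
        assert grade_metric(96.0, row).grade == Grade.OPTIMAL
        assert grade_metric(92.0, row).grade == Grade.MANDATORY
        assert grade_metric(80.0, row).grade == Grade.UNACCEPTABLE

    def test_rectum_between_tables(self):
        row_a = spec_of(default_criteria_a(), "rectum", "v_dose_abs", 36.0)
        row_b = spec_of(default_criteria_b_study(), "rectum", "v_dose_abs", 36.0)
        assert grade_metric(2.5, row_a).grade == Grade.UNACCEPTABLE
        assert grade_metric(2.5, row_b).grade == Grade.MANDATORY

    def test_bounds_inclusive(self):
        row = spec_of(default_criteria_a(), "rectum", "v_dose_abs", 36.0)
        assert grade_metric(2.0, row).grade == Grade.MANDATORY
        target = spec_of(default_criteria_a(), "ptv_psv", "v_dose_rel", 36.25)
        assert grade_metric(90.0, target).grade == Grade.MANDATORY
        assert grade_metric(85.0, target).grade == Grade.MARGINAL

    def test_urethra_never_unacceptable(self):
        row = spec_of(default_criteria_a(), "urethra", "v_dose_rel", 42.0)
        assert grade_metric(100.0, row).grade == Grade.MANDATORY
        assert grade_metric(40.0, row).grade == Grade.OPTIMAL

    @given(
        v1=st.floats(0, 120, allow_nan=False),
        v2=st.floats(0, 120, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_in_value(self, v1, v2):
        """Improving a value (per direction) never worsens the grade."""
        target = spec_of(default_criteria_a(), "ctv_psv", "v_dose_rel", 40.0)
        oar = spec_of(default_criteria_a(), "rectum", "v_dose_rel", 29.0)
        lo, hi = sorted((v1, v2))
        assert grade_metric(hi, target).grade >= grade_metric(lo, target).grade
        assert grade_metric(lo, oar).grade >= grade_metric(hi, oar).grade


class TestEvaluatePlan:
    def test_all_optimal_acceptable(self):
        a = default_criteria_a()
        ev = evaluate_plan(make_stats(a, "optimal"), a)
        assert ev.acceptable and not ev.used_marginal

    def test_marginal_target_needs_budget(self):
        a = default_criteria_a()
        stats = make_stats(a, "optimal")
        ctv = spec_of(a, "ctv_psv", "v_dose_rel", 40.0).metric
        stats.values[ctv] = 87.0  # marginal band
        ok = evaluate_plan(stats, a, MarginalBudget(used=0))
        assert ok.acceptable and ok.used_marginal
        spent = evaluate_plan(stats, a, MarginalBudget(used=1))
        assert not spent.acceptable

    def test_unacceptable_oar_rejects_despite_optimal_targets(self):
        a = default_criteria_a()
        stats = make_stats(a, "optimal")
        rectum = spec_of(a, "rectum", "v_dose_abs", 36.0).metric
        stats.values[rectum] = 5.0
        assert not evaluate_plan(stats, a).acceptable

    def test_missing_metric_errors(self):
        a = default_criteria_a()
        stats = make_stats(a, "optimal")
        del stats.values[a.rows[0].metric]
        with pytest.raises(KeyError, match="missing"):
            evaluate_plan(stats, a)

    def test_budget_charge_capacity(self):
        budget = MarginalBudget()
        assert budget.has_capacity
        budget.charge()
        assert not budget.has_capacity
        with pytest.raises(RuntimeError, match="exhausted"):
            budget.charge()


class TestDeriveCriteriaB:
    def _pool(self, table, overrides=None):
        pool = {}
        for row in table.rows:
            base = row.optimal if row.optimal is not None else row.mandatory
            pool[row.metric] = [float(base)] * 8
        for (structure, kind, level), values in (overrides or {}).items():
            pool[spec_of(table, structure, kind, level).metric] = values
        return pool

    def test_reproduces_studied_relaxations(self):
        """Quartiles at the published pool values yield the published bounds."""
        a = default_criteria_a()
        pool = self._pool(
            a,
            {
                ("ptv_psv", "d_percent", 98.0): [32.38] * 8,
                ("rectum", "v_dose_abs", 36.0): [3.04] * 8,
            },
        )
        b, changed = derive_criteria_b(pool, a)
        assert spec_of(b, "ptv_psv", "d_percent", 98.0).mandatory == 32.38
        assert spec_of(b, "rectum", "v_dose_abs", 36.0).mandatory == 3.04
        assert len(changed) == 2

    def test_linear_interpolation_quartile(self):
        a = default_criteria_a()
        pool = self._pool(a, {("ptv_psv", "d_percent", 98.0): [32.0, 32.5, 33.0, 34.0]})
        b, _ = derive_criteria_b(pool, a)
        # P25 of four values: 32.0 + 0.75 * (32.5 - 32.0) = 32.375
        assert spec_of(b, "ptv_psv", "d_percent", 98.0).mandatory == pytest.approx(32.375)

    def test_oar_quartile_below_bound_unchanged(self):
        a = default_criteria_a()
        pool = self._pool(a, {("rectum", "v_dose_abs", 36.0): [0.1, 0.2, 0.3, 0.4]})
        b, changed = derive_criteria_b(pool, a)
        assert spec_of(b, "rectum", "v_dose_abs", 36.0).mandatory == 2.0
        assert spec_of(b, "rectum", "v_dose_abs", 36.0).metric not in changed

    def test_constant_pool_min_rule(self):
        a = default_criteria_a()
        pool = self._pool(a, {("ptv_psv", "v_dose_rel", 36.25): [80.0] * 6})
        b, _ = derive_criteria_b(pool, a)
        row = spec_of(b, "ptv_psv", "v_dose_rel", 36.25)
        assert row.mandatory == 80.0
        assert row.marginal == 80.0  # clamped to preserve ordering

    def test_never_stricter_than_a_on_random_pools(self):
        rng = np.random.default_rng(11)
        a = default_criteria_a()
        for _ in range(50):
            pool = {
                row.metric: rng.uniform(0, 120, size=9).tolist() for row in a.rows
            }
            b, _ = derive_criteria_b(pool, a)
            for row_a, row_b in zip(a.rows, b.rows):
                if row_a.metric.is_target:
                    assert row_b.mandatory <= row_a.mandatory
                else:
                    assert row_b.mandatory >= row_a.mandatory

    def test_empty_pool_errors(self):
        a = default_criteria_a()
        pool = self._pool(a)
        pool[a.rows[0].metric] = []
        with pytest.raises(ValueError, match="empty"):
            derive_criteria_b(pool, a)

    def test_undersized_pool_errors(self):
        a = default_criteria_a()
        pool = self._pool(a)
        pool[a.rows[0].metric] = [90.0, 91.0]
        with pytest.raises(ValueError, match="at least 4"):
            derive_criteria_b(pool, a)


class TestCriteriaC:
    def test_b_acceptable_implies_c(self):
        b = default_criteria_b_study()
        stats = make_stats(b, "optimal")
        assert evaluate_criteria_c(stats, stats, b, True, False)
        assert evaluate_criteria_c(stats, stats, b, True, True)

    def test_no_exceptional_circumstance_when_approved_meets_b(self):
        b = default_criteria_b_study()
        stats = make_stats(b, "optimal")
        assert not evaluate_criteria_c(stats, stats, b, False, True)

    def test_identical_to_failing_approved_plan_is_acceptable(self):
        b = default_criteria_b_study()
        stats = make_stats(b, "optimal")
        assert evaluate_criteria_c(stats, stats, b, False, False)

    def test_dominance_patterns_two_metrics(self):
        """All better/worse combinations against the no-worse-anywhere rule."""
        b = default_criteria_b_study()
        approved = make_stats(b, "optimal")
        target = spec_of(b, "ptv_psv", "v_dose_rel", 36.25).metric
        oar = spec_of(b, "rectum", "v_dose_abs", 36.0).metric
        for d_target in (-1.0, 0.0, 1.0):
            for d_oar in (-0.1, 0.0, 0.1):
                cand = make_stats(b, "optimal")
                cand.values[target] += d_target
                cand.values[oar] += d_oar
                expected = d_target >= 0.0 and d_oar <= 0.0
                got = evaluate_criteria_c(cand, approved, b, False, False)
                assert got == expected, (d_target, d_oar)


class TestNesting:
    def test_a_implies_b_implies_c_on_random_statistics(self):
        """Monotone criteria nesting on 1000 random metric panels."""
        rng = np.random.default_rng(13)
        a = default_criteria_a()
        b = default_criteria_b_study()
        ranges = {
            "v_dose_rel": (0, 100),
            "v_dose_abs": (0, 12),
            "d_percent": (20, 40),
        }
        def random_stats():
            s = DoseStatistics("p", "x")
            for row in a.rows:
                lo, hi = ranges[row.metric.kind]
                s.values[row.metric] = float(rng.uniform(lo, hi))
            return s

        for _ in range(1000):
            stats = random_stats()
            approved = random_stats()
            acc_a = evaluate_plan(stats, a).acceptable
            acc_b = evaluate_plan(stats, b).acceptable
            app_b = evaluate_plan(approved, b).acceptable
            acc_c = evaluate_criteria_c(stats, approved, b, acc_b, app_b)
            assert (not acc_a or acc_b) and (not acc_b or acc_c)
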