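"""Grading a metric panel against the clinical-goal and benchmark tables.

Every metric is graded optimal / mandatory / marginal / unacceptable against
its constraint row; a plan is acceptable when all organs at risk grade
mandatory-or-better and the targets grade mandatory-or-better (marginal
coverage is allowed once per course).  The same panel is graded under the
clinical goals (Criteria A) and the benchmark-relaxed table (Criteria B).
"""

from dprfeas import (
    DoseStatistics,
    default_criteria_a,
    default_criteria_b_study,
    evaluate_plan,
)

table_a = default_criteria_a()
table_b = default_criteria_b_study()

# a plan with slightly soft target coverage and a warm rectum
values = {
    ("ctv_psv", 40.0): 96.0,
    ("ptv_psv", 36.25): 91.0,
    ("ptv_psv", 98.0): 33.0,   # below the 33.71 Gy clinical goal
    ("bladder", 37.0): 2.1,
    ("bladder", 18.1): 12.0,
    ("rectum", 36.0): 2.5,     # above the 2 cm3 clinical goal
    ("rectum", 29.0): 6.0,
    ("rectum", 18.1): 20.0,
    ("bowel", 30.0): 0.0,
    ("bowel", 18.1): 0.4,
    ("urethra", 42.0): 80.0,
}
stats = DoseStatistics("example_plan", "daily_3")
for row in table_a.rows:
    stats.values[row.metric] = values[(row.metric.structure, row.metric.level)]

for table in (table_a, table_b):
    ev = evaluate_plan(stats, table)
    print(f"Criteria {table.label}: acceptable = {ev.acceptable}")
    for g in ev.grades:
        print(f"  {g.metric.label():28s} {g.value:7.2f}  -> {g.grade.name.lower()}")
    print()
print("The PTV D98% and rectum V36Gy violations are unacceptable under the")
print("clinical goals but tolerated by the empirically relaxed benchmark.")
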