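"""Repository assessment of one course: which old plans would have worked?

Simulates one five-fraction course, then at every fraction propagates the
day's contours backwards onto each stored plan (offline reference plus all
earlier online plans), evaluates the metric panel on that plan's dose, and
prints the acceptability heatmap: rows are stored plans, columns fractions.
"""

from dprfeas import (
    CohortConfig,
    acceptability_heatmap,
    assess_course,
    default_criteria_a,
    derive_criteria_b,
    pool_ccpb,
    simulate_cohort,
)
from dprfeas.pipeline import compute_benchmark

config = CohortConfig(n_patients=1, corrupted=(), swelling_rates={}, seed=23)
course = simulate_cohort(config)[0].course
table_a = default_criteria_a()

ccpb_stats, _, verif = compute_benchmark([course], table_a.metrics)
table_b, _ = derive_criteria_b(pool_ccpb(verif).values, table_a)
matrix = assess_course(
    course, table_a, table_b,
    {i: s for (_, i), s in ccpb_stats.items()},
)

print(acceptability_heatmap(matrix).to_string())
counts = matrix.counts()
print(f"\nfractions with >=1 acceptable stored plan: "
      f"A {counts.n_a}/{counts.total}, B {counts.n_b}/{counts.total}, "
      f"C {counts.n_c}/{counts.total}")
print("acceptable_A cells satisfy the clinical goals outright; acceptable_B")
print("only the relaxed benchmark; acceptable_C_exceptional only matches an")
print("approved plan that itself violated the benchmark that day.")
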