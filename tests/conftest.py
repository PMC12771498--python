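"""Shared fixtures: small grids, a reference patient, a tiny simulated cohort."""

import numpy as np
import pytest

from dprfeas.criteria import default_criteria_a, derive_criteria_b
from dprfeas.ccpb import pool_ccpb
from dprfeas.dpr import assess_course
from dprfeas.geometry import Grid, Mask, rasterize_ellipsoid
from dprfeas.pipeline import compute_benchmark
from dprfeas.synthetic import CohortConfig, make_reference_patient, simulate_cohort


@pytest.fixture
def grid1mm():
    return Grid(shape=(25, 25, 25), spacing=(1.0, 1.0, 1.0), origin=(-12.0, -12.0, -12.0))


@pytest.fixture
def ball(grid1mm):
    return rasterize_ellipsoid((0.0, 0.0, 0.0), (6.0, 6.0, 6.0), grid1mm)


@pytest.fixture(scope="session")
def reference_patient():
    cfg = CohortConfig(seed=5)
    rng = np.random.default_rng([5, 0])
    return cfg, make_reference_patient(cfg, 0, rng)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Two patients, three fractions, one corrupted fraction (P2 fx2)."""
    cfg = CohortConfig(
        n_patients=2, n_fractions=3, corrupted=((1, 2),), swelling_rates={}, seed=12
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture(scope="session")
def assessed_tiny(tiny_cohort):
    """The tiny cohort pushed through benchmark, Criteria-B derivation and
    full repository assessment."""
    _, sims = tiny_cohort
    courses = [sc.course for sc in sims]
    table_a = default_criteria_a()
    ccpb, daily, verif = compute_benchmark(courses, table_a.metrics)
    table_b, _ = derive_criteria_b(pool_ccpb(verif).values, table_a)
    matrices = [
        assess_course(
            c,
            table_a,
            table_b,
            {i: s for (p, i), s in ccpb.items() if p == c.patient_id},
        )
        for c in courses
    ]
    return {
        "courses": courses,
        "table_a": table_a,
        "table_b": table_b,
        "ccpb": ccpb,
        "daily": daily,
        "verif": verif,
        "matrices": matrices,
    }


def random_mask(grid: Grid, rng: np.random.Generator, p: float = 0.3) -> Mask:
    voxels = rng.random(grid.shape) < p
    if not voxels.any():
        voxels[tuple(s // 2 for s in grid.shape)] = True
    return Mask(grid, voxels)
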