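"""Dose-volume metric extraction: V_xGy (absolute / relative) and D_p%.

The metric panel mirrors the online clinical-goal sheet for five-fraction
prostate treatments: target coverage metrics (CTV/PTV V_dose, PTV D_98%) and
OAR sparing metrics (bladder, rectum, bowel, urethra V_dose).

Numerical conventions (stated because treatment-planning systems differ):

* V metrics use an *inclusive* comparison, ``dose >= threshold``, which makes
  uniform-dose boundary cases well defined.
* D_p% is the exact voxel-dose order statistic: the largest dose ``d`` such
  that at least ``p`` % of the structure's voxels receive ``>= d``.  No
  interpolation between voxel values; this matches a brute-force enumeration
  oracle exactly, and interpolated variants differ by less than the voxel-dose
  granularity.
* When a mask lives on a different lattice from the dose, the *mask* is
  resampled (nearest-neighbour) to the dose grid; dose values are never
  resampled.  The denominator of relative metrics is the resampled mask's
  volume, keeping numerator and denominator consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import Grid, Mask, StructureSet, resample_mask

__all__ = [
    "DoseGrid",
    "MetricSpec",
    "DoseStatistics",
    "v_dose",
    "d_percent",
    "compute_dose_statistics",
    "statistics_to_frame",
]

_KINDS = ("v_dose_abs", "v_dose_rel", "d_percent")
_DIRECTIONS = ("target_coverage", "oar_sparing")


@dataclass
class DoseGrid:
    """A 3D absorbed-dose field (Gy) on a regular grid."""

    grid: Grid
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.shape != self.grid.shape:
            raise ValueError(
                f"dose array shape {arr.shape} does not match grid shape {self.grid.shape}"
            )
        self.values = arr

    @property
    def max_dose(self) -> float:
        return float(self.values.max())


@dataclass(frozen=True)
class MetricSpec:
    """One named dose-volume quantity of one structure.

    ``kind`` is ``v_dose_abs`` (cm³ receiving >= level Gy), ``v_dose_rel``
    (% of structure volume receiving >= level Gy) or ``d_percent`` (Gy
    covering level % of the volume).  ``direction`` states which way is
    better: ``target_coverage`` (higher) or ``oar_sparing`` (lower).
    """

    structure: str
    kind: str
    level: float
    direction: str

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown metric kind {self.kind!r}; expected one of {_KINDS}")
        if self.direction not in _DIRECTIONS:
            raise ValueError(
                f"unknown direction {self.direction!r}; expected one of {_DIRECTIONS}"
            )
        object.__setattr__(self, "level", float(self.level))
        if self.level <= 0:
            raise ValueError("metric level must be positive")
        if self.kind == "d_percent" and not (0 < self.level <= 100):
            raise ValueError("d_percent level must be in (0, 100]")

    @property
    def units(self) -> str:
        return {"v_dose_abs": "cm3", "v_dose_rel": "%", "d_percent": "Gy"}[self.kind]

    @property
    def is_target(self) -> bool:
        return self.direction == "target_coverage"

    def label(self) -> str:
        lvl = f"{self.level:g}"
        if self.kind == "d_percent":
            return f"{self.structure} D_{lvl}% [Gy]"
        unit = "%" if self.kind == "v_dose_rel" else "cm3"
        return f"{self.structure} V_{lvl}Gy [{unit}]"


@dataclass
class DoseStatistics:
    """The metric panel evaluated for one plan on one anatomy."""

    plan_id: str
    anatomy_id: str
    values: dict[MetricSpec, float] = field(default_factory=dict)

    def get(self, spec: MetricSpec) -> float:
        try:
            return self.values[spec]
        except KeyError:
            raise KeyError(f"metric {spec.label()} missing from dose statistics") from None

    def __iter__(self):
        return iter(self.values.items())


def _mask_doses(dose: DoseGrid, mask: Mask) -> np.ndarray:
    """Within-structure voxel dose multiset, after mask resampling if needed."""
    if mask.grid.frame_id != dose.grid.frame_id:
        raise ValueError(
            f"dose frame {dose.grid.frame_id!r} != mask frame {mask.grid.frame_id!r}; "
            "propagate the mask first"
        )
    m = resample_mask(mask, dose.grid)
    if m.is_empty:
        raise ValueError("undefined metric: structure mask is empty on the dose grid")
    return dose.values[m.voxels]


def v_dose(dose: DoseGrid, mask: Mask, threshold: float, mode: str = "rel") -> float:
    """Structure volume receiving at least ``threshold`` Gy.

    ``mode='abs'`` returns cm³; ``mode='rel'`` returns percent of the
    structure volume.  The comparison is inclusive (``dose >= threshold``).
    """
    if mode not in ("abs", "rel"):
        raise ValueError("mode must be 'abs' or 'rel'")
    doses = _mask_doses(dose, mask)
    n_hot = int((doses >= threshold).sum())
    if mode == "abs":
        return n_hot * dose.grid.voxel_volume_mm3 / 1000.0
    return 100.0 * n_hot / doses.size


def d_percent(dose: DoseGrid, mask: Mask, p: float) -> float:
    """Largest dose received by at least ``p`` % of the structure's volume.

    Computed as an exact order statistic of the within-mask dose multiset:
    with ``n`` voxels, the ``ceil(p * n / 100)``-th largest value.  ``p=100``
    yields the minimum dose within the mask.
    """
    if not (0 < p <= 100):
        raise ValueError("p must be in (0, 100]")
    doses = np.sort(_mask_doses(dose, mask))[::-1]
    k = int(math.ceil(p * doses.size / 100.0 - 1e-12))
    k = min(max(k, 1), doses.size)
    return float(doses[k - 1])


def evaluate_metric(dose: DoseGrid, mask: Mask, spec: MetricSpec) -> float:
    if spec.kind == "v_dose_abs":
        return v_dose(dose, mask, spec.level, mode="abs")
    if spec.kind == "v_dose_rel":
        return v_dose(dose, mask, spec.level, mode="rel")
    return d_percent(dose, mask, spec.level)


def compute_dose_statistics(
    dose: DoseGrid,
    structures: StructureSet,
    specs: Iterable[MetricSpec],
    plan_id: str = "",
    anatomy_id: str = "",
) -> DoseStatistics:
    """Evaluate every metric spec on one dose/anatomy pair (deterministic)."""
    stats = DoseStatistics(plan_id=plan_id, anatomy_id=anatomy_id)
    for spec in specs:
        if spec.structure not in structures:
            raise ValueError(
                f"structure {spec.structure!r} required by metric {spec.label()} "
                "is missing from the structure set"
            )
        stats.values[spec] = evaluate_metric(dose, structures[spec.structure], spec)
    return stats


def statistics_to_frame(stats_list: Sequence[DoseStatistics]) -> pd.DataFrame:
    """Long-format table: one row per (plan, anatomy, structure, metric)."""
    rows = []
    for st in stats_list:
        for spec, value in st:
            rows.append(
                {
                    "plan_id": st.plan_id,
                    "anatomy_id": st.anatomy_id,
                    "structure": spec.structure,
                    "metric": spec.label(),
                    "kind": spec.kind,
                    "level": spec.level,
                    "value": value,
                    "units": spec.units,
                }
            )
    return pd.DataFrame(rows)
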