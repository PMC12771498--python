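"""File interchange: NIfTI volumes, JSON cohort manifests, CSV reports.

Native interchange is NIfTI + JSON + CSV.  NIfTI affines are restricted to
axis-aligned, positive-diagonal forms (spacing on the diagonal, origin in the
translation column) so that grids are unambiguous; DICOM-RT is import-only
and quarantined in :mod:`dprfeas.dicom_rt`.  Every CSV written by the package
carries its column schema in a leading ``#`` comment line; the pipeline never
mutates its input files.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .ccpb import FractionRecord
from .dpr import CourseRecord, PlanRecord
from .geometry import DEFAULT_ROLES, Grid, Mask, StructureSet
from .metrics import DoseGrid

__all__ = [
    "save_mask",
    "load_mask",
    "save_dose",
    "load_dose",
    "write_cohort",
    "read_manifest",
    "write_csv",
    "read_csv",
]


def _affine(grid: Grid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def _grid_from_affine(aff: np.ndarray, shape, frame_id: str) -> Grid:
    rot = aff[:3, :3]
    if not np.allclose(rot, np.diag(np.diag(rot)), atol=1e-6):
        raise ValueError("only axis-aligned NIfTI affines are supported")
    spacing = np.diag(rot)
    if (spacing <= 0).any():
        raise ValueError("NIfTI affine must have positive diagonal spacing")
    return Grid(
        shape=tuple(int(s) for s in shape),
        spacing=tuple(float(s) for s in spacing),
        origin=tuple(float(o) for o in aff[:3, 3]),
        frame_id=frame_id,
    )


def save_mask(mask: Mask, path) -> None:
    img = nib.Nifti1Image(mask.voxels.astype(np.uint8), _affine(mask.grid))
    nib.save(img, str(path))


def load_mask(path, frame_id: str = "world") -> Mask:
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape, frame_id)
    return Mask(grid, np.asarray(img.dataobj) > 0)


def save_dose(dose: DoseGrid, path) -> None:
    img = nib.Nifti1Image(dose.values.astype(np.float32), _affine(dose.grid))
    nib.save(img, str(path))


def load_dose(path, frame_id: str = "world") -> DoseGrid:
    img = nib.load(str(path))
    grid = _grid_from_affine(img.affine, img.shape, frame_id)
    return DoseGrid(grid, np.asarray(img.dataobj, dtype=float))


# ---------------------------------------------------------------------------
# cohort manifests

def _write_anatomy(anatomy: StructureSet, directory: Path, base: Path) -> dict:
    directory.mkdir(parents=True, exist_ok=True)
    entry = {"frame_id": anatomy.frame_id, "roles": dict(anatomy.roles), "structures": {}}
    for name, mask in anatomy.structures.items():
        fp = directory / f"{name}.nii.gz"
        save_mask(mask, fp)
        entry["structures"][name] = str(fp.relative_to(base))
    return entry


def _read_anatomy(entry: dict, base: Path, where: str) -> StructureSet:
    structures = {}
    frame_id = entry.get("frame_id", "world")
    for name, rel in entry["structures"].items():
        fp = base / rel
        if not fp.exists():
            raise FileNotFoundError(f"{where}: structure file missing: {fp}")
        structures[name] = load_mask(fp, frame_id=frame_id)
    try:
        return StructureSet(
            structures=structures,
            roles=dict(entry.get("roles") or {n: DEFAULT_ROLES[n] for n in structures}),
            frame_id=frame_id,
        )
    except (ValueError, KeyError) as exc:
        raise ValueError(f"{where}: invalid structure set: {exc}") from exc


def write_cohort(courses: Sequence[CourseRecord], out_dir) -> Path:
    """Write a cohort to disk (NIfTI volumes + manifest.json); returns the
    manifest path.  Layout: one directory per patient, one per anatomy."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"patients": []}
    for course in courses:
        pdir = out / course.patient_id
        ct = course.ct_ref
        ct_dose_fp = pdir / "ct_ref" / "dose.nii.gz"
        ct_dose_fp.parent.mkdir(parents=True, exist_ok=True)
        save_dose(ct.dose, ct_dose_fp)
        patient = {
            "id": course.patient_id,
            "ct_ref": {
                "plan_id": ct.plan_id,
                "dose": str(ct_dose_fp.relative_to(out)),
                "anatomy": _write_anatomy(ct.planning_anatomy, pdir / "ct_ref" / "anatomy", out),
            },
            "fractions": [],
        }
        for fraction in course.fractions:
            fdir = pdir / f"fx{fraction.index}"
            entry = {
                "index": fraction.index,
                "workflow": fraction.workflow,
                "excluded": fraction.excluded,
                "daily": _write_anatomy(fraction.daily, fdir / "daily", out),
                "verif": _write_anatomy(fraction.verif, fdir / "verif", out),
            }
            plan = course.plan_for_fraction(fraction.index)
            if plan is not None:
                dose_fp = fdir / "plan_dose.nii.gz"
                save_dose(plan.dose, dose_fp)
                entry["plan_id"] = plan.plan_id
                entry["plan_dose"] = str(dose_fp.relative_to(out))
            patient["fractions"].append(entry)
        manifest["patients"].append(patient)
    manifest_fp = out / "manifest.json"
    with open(manifest_fp, "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")
    return manifest_fp


def read_manifest(path) -> list[CourseRecord]:
    """Load and validate a cohort manifest into in-memory course records.

    Online plans are re-associated with their fraction's daily anatomy (the
    anatomy they were optimized for).  Errors carry the JSON location of the
    offending entry."""
    path = Path(path)
    base = path.parent
    with open(path) as fh:
        manifest = json.load(fh)
    if "patients" not in manifest:
        raise ValueError("/patients: missing from manifest")
    courses = []
    for i, patient in enumerate(manifest["patients"]):
        where = f"/patients/{i}"
        for key in ("id", "ct_ref", "fractions"):
            if key not in patient:
                raise ValueError(f"{where}/{key}: missing from manifest")
        ct_anatomy = _read_anatomy(
            patient["ct_ref"]["anatomy"], base, f"{where}/ct_ref/anatomy"
        )
        ct_dose_fp = base / patient["ct_ref"]["dose"]
        if not ct_dose_fp.exists():
            raise FileNotFoundError(f"{where}/ct_ref/dose: file missing: {ct_dose_fp}")
        plans = [
            PlanRecord(
                plan_id=patient["ct_ref"].get("plan_id", "DPR_0"),
                dose=load_dose(ct_dose_fp, frame_id=ct_anatomy.frame_id),
                planning_anatomy=ct_anatomy,
                source_fraction=0,
            )
        ]
        fractions = []
        for j, entry in enumerate(patient["fractions"]):
            fwhere = f"{where}/fractions/{j}"
            daily = _read_anatomy(entry["daily"], base, f"{fwhere}/daily")
            verif = _read_anatomy(entry["verif"], base, f"{fwhere}/verif")
            fraction = FractionRecord(
                index=int(entry["index"]),
                daily=daily,
                verif=verif,
                approved_plan_id=entry.get("plan_id", ""),
                workflow=entry.get("workflow", "ATS"),
                excluded=bool(entry.get("excluded", False)),
            )
            fractions.append(fraction)
            if entry.get("plan_dose"):
                dose_fp = base / entry["plan_dose"]
                if not dose_fp.exists():
                    raise FileNotFoundError(f"{fwhere}/plan_dose: file missing: {dose_fp}")
                plans.append(
                    PlanRecord(
                        plan_id=entry.get("plan_id", f"DPR_{entry['index']}"),
                        dose=load_dose(dose_fp, frame_id=daily.frame_id),
                        planning_anatomy=daily,
                        source_fraction=int(entry["index"]),
                    )
                )
        courses.append(
            CourseRecord(patient_id=patient["id"], fractions=fractions, plans=plans)
        )
    return courses


# ---------------------------------------------------------------------------
# CSV reports

def write_csv(frame: pd.DataFrame, path, index: bool = False) -> None:
    """Write a report CSV with its column schema in a header comment."""
    path = Path(path)
    cols = ([frame.index.name] if index and frame.index.name else []) + list(
        map(str, frame.columns)
    )
    with open(path, "w") as fh:
        fh.write("# columns: " + ", ".join(cols) + "\n")
        frame.to_csv(fh, index=index, lineterminator="\n")


def read_csv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)
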