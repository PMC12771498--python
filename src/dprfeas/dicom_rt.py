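"""Optional DICOM-RT import: RTDOSE grids and RTSTRUCT contour rasterization.

Import-only, and deliberately narrow: axis-aligned orientations, regular
slice spacing.  RTDOSE values are scaled by ``DoseGridScaling``; RTSTRUCT
contour polygons are rasterized slice-by-slice by point-in-polygon tests on
voxel centers (matplotlib's path machinery), the same voxel-center membership
convention used everywhere else in the package.
"""

from __future__ import annotations

import numpy as np
import pydicom
from matplotlib.path import Path as MplPath

from .geometry import DEFAULT_ROLES, Grid, Mask, StructureSet
from .metrics import DoseGrid

__all__ = ["load_rtdose", "load_rtstruct"]

_AXIS_ALIGNED = (1.0, 0.0, 0.0, 0.0, 1.0, 0.0)


def _require_axis_aligned(ds) -> None:
    iop = tuple(float(v) for v in ds.ImageOrientationPatient)
    if not np.allclose(iop, _AXIS_ALIGNED, atol=1e-6):
        raise ValueError(
            f"only axis-aligned orientations are supported, got {iop}"
        )


def load_rtdose(source, frame_id: str = "world") -> DoseGrid:
    """Read an RTDOSE dataset (path or pydicom Dataset) into a dose grid.

    The DICOM pixel array is ordered (frame, row, col) = (z, y, x); it is
    transposed to this package's (x, y, z) axis order.
    """
    ds = source if isinstance(source, pydicom.Dataset) else pydicom.dcmread(str(source))
    _require_axis_aligned(ds)
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    values = ds.pixel_array.astype(float) * scaling  # (z, y, x)
    values = np.transpose(values, (2, 1, 0))
    row_spacing, col_spacing = (float(v) for v in ds.PixelSpacing)
    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    dz = np.diff(offsets)
    if offsets.size > 1 and not np.allclose(dz, dz[0], atol=1e-6):
        raise ValueError("irregular GridFrameOffsetVector is not supported")
    z_spacing = float(dz[0]) if offsets.size > 1 else 1.0
    if z_spacing <= 0:
        raise ValueError("GridFrameOffsetVector must be increasing")
    origin = tuple(float(v) for v in ds.ImagePositionPatient)
    grid = Grid(
        shape=values.shape,
        spacing=(col_spacing, row_spacing, z_spacing),
        origin=origin,
        frame_id=frame_id,
    )
    return DoseGrid(grid, values)


def _rasterize_contours(contours, grid: Grid) -> np.ndarray:
    """Rasterize per-slice closed polygons by voxel-center membership."""
    voxels = np.zeros(grid.shape, dtype=bool)
    ax = grid.axes()
    xx, yy = np.meshgrid(ax[0], ax[1], indexing="ij")
    plane_pts = np.stack([xx.ravel(), yy.ravel()], axis=1)
    for contour in contours:
        pts = np.asarray(contour, dtype=float).reshape(-1, 3)
        z = pts[:, 2].mean()
        k = int(np.rint((z - grid.origin[2]) / grid.spacing[2]))
        if not (0 <= k < grid.shape[2]):
            continue
        inside = MplPath(pts[:, :2]).contains_points(plane_pts)
        voxels[:, :, k] |= inside.reshape(grid.shape[0], grid.shape[1])
    return voxels


def load_rtstruct(
    source,
    grid: Grid,
    names: dict[str, str] | None = None,
    roles: dict[str, str] | None = None,
) -> StructureSet:
    """Rasterize an RTSTRUCT dataset onto a grid.

    ``names`` maps DICOM ROI names to this package's structure vocabulary
    (case-insensitive match on the DICOM side); ROIs without a mapping are
    skipped.  With ``names=None``, ROI names are lower-cased and kept when
    they already are vocabulary members.
    """
    ds = source if isinstance(source, pydicom.Dataset) else pydicom.dcmread(str(source))
    roi_names = {
        int(roi.ROINumber): str(roi.ROIName) for roi in ds.StructureSetROISequence
    }
    lookup = {k.lower(): v for k, v in (names or {}).items()}
    structures = {}
    for roi_contour in ds.ROIContourSequence:
        dicom_name = roi_names.get(int(roi_contour.ReferencedROINumber), "")
        if names is not None:
            target = lookup.get(dicom_name.lower())
        else:
            target = dicom_name.lower()
        if target is None or target not in DEFAULT_ROLES:
            continue
        contours = [
            c.ContourData
            for c in getattr(roi_contour, "ContourSequence", [])
            if getattr(c, "ContourGeometricType", "CLOSED_PLANAR") == "CLOSED_PLANAR"
        ]
        if not contours:
            continue
        structures[target] = Mask(grid, _rasterize_contours(contours, grid))
    if not structures:
        raise ValueError("RTSTRUCT contains no mappable structures")
    return StructureSet(structures=structures, roles=roles or {}, frame_id=grid.frame_id)
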