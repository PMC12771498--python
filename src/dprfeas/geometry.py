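"""Regular-grid geometry: masks, margin expansion, rigid transforms, registration.

Conventions used throughout the package
---------------------------------------
* Voxel-center convention: the physical (mm) coordinate of voxel index
  ``(i, j, k)`` is ``origin + index * spacing``, axis-wise, 0-based.
* Axes are ``(x, y, z)`` = (left-right, posterior-anterior, inferior-superior);
  ``+y`` is anterior and ``+z`` is superior.
* Masks are strictly binary and defined by voxel-center membership (no partial
  volume).  Mask resampling is nearest-neighbour so masks stay binary; dose is
  the physical field and is interpolated trilinearly where it must move
  (see :mod:`dprfeas.ccpb`).
* Registrations between fraction frames are translation-only by default:
  online prostate matching is dominated by translation, and rotations are
  accepted only as user-supplied full rigid transforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

__all__ = [
    "STRUCTURE_VOCABULARY",
    "DEFAULT_ROLES",
    "Grid",
    "Mask",
    "RigidTransform",
    "StructureSet",
    "rasterize_ellipsoid",
    "expand_margin",
    "apply_rigid",
    "resample_mask",
    "estimate_registration",
    "volume_cc",
]

#: Controlled vocabulary of structure names used by the criteria tables.
STRUCTURE_VOCABULARY = frozenset(
    {
        "prostate",
        "sv",
        "ctv_psv",
        "ctv_sv",
        "ptv_psv",
        "ptv_sv",
        "bladder",
        "rectum",
        "bowel",
        "urethra",
    }
)

#: Default role tag per structure name (target vs organ at risk).
DEFAULT_ROLES: Mapping[str, str] = {
    "prostate": "target",
    "sv": "target",
    "ctv_psv": "target",
    "ctv_sv": "target",
    "ptv_psv": "target",
    "ptv_sv": "target",
    "bladder": "oar",
    "rectum": "oar",
    "bowel": "oar",
    "urethra": "oar",
}


@dataclass(frozen=True)
class Grid:
    """A regular 3D lattice with a physical frame of reference.

    Parameters
    ----------
    shape
        Number of voxels per axis (strictly positive integers).
    spacing
        Voxel pitch in mm per axis (strictly positive).
    origin
        Physical mm coordinate of the *center* of voxel ``(0, 0, 0)``.
    frame_id
        Label of the frame of reference the grid lives in.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    frame_id: str = "world"

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("Grid shape, spacing and origin must be length-3")
        if any(s <= 0 for s in self.shape):
            raise ValueError(f"Grid shape must be strictly positive, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"Grid spacing must be strictly positive, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def axes(self) -> list[np.ndarray]:
        """Per-axis physical coordinates of voxel centers."""
        return [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]

    def centers(self) -> np.ndarray:
        """All voxel-center coordinates as an ``(N, 3)`` array (C order)."""
        ax = self.axes()
        xx, yy, zz = np.meshgrid(*ax, indexing="ij")
        return np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Fractional voxel indices of physical points."""
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def same_lattice(self, other: "Grid") -> bool:
        """True when shapes, spacings and origins coincide (frames may differ)."""
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class Mask:
    """A binary structure on a :class:`Grid`."""

    grid: Grid
    voxels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.shape != self.grid.shape:
            raise ValueError(
                f"mask array shape {arr.shape} does not match grid shape {self.grid.shape}"
            )
        if arr.dtype != bool:
            vals = np.unique(arr)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("mask values must be exactly 0 or 1")
            arr = arr.astype(bool)
        self.voxels = arr

    @property
    def count(self) -> int:
        return int(self.voxels.sum())

    @property
    def is_empty(self) -> bool:
        return not self.voxels.any()

    def center_of_mass(self) -> np.ndarray:
        """Physical (mm) centroid of the voxel set."""
        if self.is_empty:
            raise ValueError("center of mass of an empty mask is undefined")
        idx_com = np.array(ndimage.center_of_mass(self.voxels))
        return self.grid.index_to_world(idx_com)


@dataclass
class RigidTransform:
    """Rigid map between frames: ``y = R @ x + t`` (mm).

    The rotation must be orthonormal with determinant +1; the identity is the
    common case (translation-only registrations).
    """

    translation: np.ndarray
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    source_frame: str = "world"
    target_frame: str = "world"

    def __post_init__(self) -> None:
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation must be orthonormal")
        if not np.isclose(np.linalg.det(self.rotation), 1.0, atol=1e-8):
            raise ValueError("rotation must be proper (determinant +1)")

    @classmethod
    def identity(cls, frame: str = "world") -> "RigidTransform":
        return cls(np.zeros(3), np.eye(3), frame, frame)

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rot_inv = self.rotation.T
        return RigidTransform(
            -rot_inv @ self.translation, rot_inv, self.target_frame, self.source_frame
        )

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """The transform ``self ∘ first`` (apply ``first``, then ``self``)."""
        if first.target_frame != self.source_frame:
            raise ValueError(
                f"cannot compose: inner target frame {first.target_frame!r} "
                f"!= outer source frame {self.source_frame!r}"
            )
        return RigidTransform(
            self.rotation @ first.translation + self.translation,
            self.rotation @ first.rotation,
            first.source_frame,
            self.target_frame,
        )


@dataclass
class StructureSet:
    """Named binary structures sharing one grid, with target/OAR role tags."""

    structures: dict[str, Mask]
    roles: dict[str, str] = field(default_factory=dict)
    frame_id: str = "world"

    def __post_init__(self) -> None:
        if not self.structures:
            raise ValueError("structure set must contain at least one structure")
        unknown = set(self.structures) - STRUCTURE_VOCABULARY
        if unknown:
            raise ValueError(
                f"unknown structure name(s) {sorted(unknown)}; "
                f"allowed: {sorted(STRUCTURE_VOCABULARY)}"
            )
        first = next(iter(self.structures.values())).grid
        for m in self.structures.values():
            if not m.grid.same_lattice(first) or m.grid.frame_id != first.frame_id:
                raise ValueError("all masks in a structure set must share one grid")
        if not self.roles:
            self.roles = {n: DEFAULT_ROLES[n] for n in self.structures}
        bad_roles = {r for r in self.roles.values()} - {"target", "oar"}
        if bad_roles:
            raise ValueError(f"roles must be 'target' or 'oar', got {sorted(bad_roles)}")
        if self.frame_id != first.frame_id:
            raise ValueError(
                f"structure set frame {self.frame_id!r} != grid frame {first.frame_id!r}"
            )

    @property
    def grid(self) -> Grid:
        return next(iter(self.structures.values())).grid

    def __getitem__(self, name: str) -> Mask:
        try:
            return self.structures[name]
        except KeyError:
            raise KeyError(f"structure {name!r} not present in structure set") from None

    def __contains__(self, name: str) -> bool:
        return name in self.structures


def rasterize_ellipsoid(
    center: tuple[float, float, float],
    radii: tuple[float, float, float],
    grid: Grid,
) -> Mask:
    """Rasterize an axis-aligned ellipsoid onto a grid by voxel-center membership.

    A voxel belongs to the mask when its center ``x`` satisfies
    ``sum(((x - center) / radii) ** 2) <= 1``.

    Raises
    ------
    ValueError
        If a radius is non-positive or the ellipsoid contains no voxel center.
    """
    center = np.asarray(center, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if (radii <= 0).any():
        raise ValueError(f"ellipsoid radii must be strictly positive, got {radii}")
    ax = grid.axes()
    terms = [((ax[a] - center[a]) / radii[a]) ** 2 for a in range(3)]
    q = (
        terms[0][:, None, None]
        + terms[1][None, :, None]
        + terms[2][None, None, :]
    )
    voxels = q <= 1.0 + 1e-12
    if not voxels.any():
        raise ValueError("empty structure: ellipsoid contains no voxel center of the grid")
    return Mask(grid, voxels)


def _margin_structuring_element(
    margins: np.ndarray, spacing: tuple[float, float, float]
) -> np.ndarray:
    """Binary structuring element for a (possibly direction-dependent) margin.

    ``margins`` is ``(x-, x+, y-, y+, z-, z+)`` in mm.  An offset ``d`` (mm)
    is inside the margin when ``sum((d_a / m_a(sign d_a)) ** 2) <= 1`` with the
    per-direction margin on each axis — the ellipsoidal expansion used for
    CTV-to-PTV margins; a zero margin forbids any motion along that direction.
    """
    half = [
        int(np.ceil(max(margins[2 * a], margins[2 * a + 1]) / spacing[a]))
        for a in range(3)
    ]
    offsets = np.meshgrid(
        *[np.arange(-h, h + 1) * spacing[a] for a, h in enumerate(half)], indexing="ij"
    )
    q = np.zeros(offsets[0].shape)
    feasible = np.ones(offsets[0].shape, dtype=bool)
    for a in range(3):
        d = offsets[a]
        m = np.where(d >= 0, margins[2 * a + 1], margins[2 * a])
        with np.errstate(divide="ignore", invalid="ignore"):
            term = (d / m) ** 2
        zero_margin = m == 0
        feasible &= ~(zero_margin & (d != 0))
        term = np.where(d == 0, 0.0, term)
        term = np.where(zero_margin, 0.0, term)
        q += term
    return feasible & (q <= 1.0 + 1e-9)


def expand_margin(mask: Mask, margins) -> Mask:
    """Expand a mask by anisotropic margins ``(x-, x+, y-, y+, z-, z+)`` in mm.

    The output contains every voxel whose center lies within the (ellipsoidal,
    direction-dependent) margin of the input voxel set; it is always a superset
    of the input and is monotone in the margins.
    """
    margins = np.asarray(margins, dtype=float)
    if np.isscalar(margins) or margins.ndim == 0:
        margins = np.full(6, float(margins))
    if margins.shape == (3,):
        margins = np.repeat(margins, 2)
    if margins.shape != (6,):
        raise ValueError("margins must be 6 values (x-, x+, y-, y+, z-, z+) or 3 or 1")
    if (margins < 0).any():
        raise ValueError(f"margins must be non-negative, got {margins}")
    if not margins.any():
        return Mask(mask.grid, mask.voxels.copy())
    elem = _margin_structuring_element(margins, mask.grid.spacing)
    out = ndimage.binary_dilation(mask.voxels, structure=elem)
    return Mask(mask.grid, out)


def apply_rigid(mask: Mask, transform: RigidTransform, target_grid: Grid) -> Mask:
    """Resample a mask through a rigid transform onto a target grid.

    Nearest-neighbour sampling: each target voxel center is pulled back through
    the inverse transform and takes the value of the nearest source voxel;
    points mapping outside the source grid are dropped (zero).
    """
    if transform.source_frame != mask.grid.frame_id:
        raise ValueError(
            f"transform source frame {transform.source_frame!r} does not match "
            f"mask frame {mask.grid.frame_id!r}"
        )
    if transform.target_frame != target_grid.frame_id:
        raise ValueError(
            f"transform target frame {transform.target_frame!r} does not match "
            f"target grid frame {target_grid.frame_id!r}"
        )
    inv = transform.inverse()
    src_pts = inv.apply_points(target_grid.centers())
    idx = np.rint(mask.grid.world_to_index(src_pts)).astype(int)
    shape = np.asarray(mask.grid.shape)
    valid = ((idx >= 0) & (idx < shape)).all(axis=1)
    out = np.zeros(int(np.prod(target_grid.shape)), dtype=bool)
    iv = idx[valid]
    out[valid] = mask.voxels[iv[:, 0], iv[:, 1], iv[:, 2]]
    return Mask(target_grid, out.reshape(target_grid.shape))


def resample_mask(mask: Mask, grid: Grid) -> Mask:
    """Nearest-neighbour resample within one frame (identity transform)."""
    if mask.grid.frame_id != grid.frame_id:
        raise ValueError(
            f"cannot resample across frames {mask.grid.frame_id!r} -> {grid.frame_id!r} "
            "without a transform; use apply_rigid"
        )
    if mask.grid.same_lattice(grid):
        return mask
    return apply_rigid(mask, RigidTransform.identity(grid.frame_id), grid)


def estimate_registration(
    daily: StructureSet, repo: StructureSet, anchor: str = "prostate"
) -> RigidTransform:
    """Translation-only registration aligning an anchor structure's centroid.

    Returns the transform mapping points in the daily frame to the repository
    (plan) frame such that the anchor centers of mass coincide.
    """
    for name, ss in (("daily", daily), ("repository", repo)):
        if anchor not in ss:
            raise ValueError(f"anchor structure {anchor!r} missing from {name} set")
        if ss[anchor].is_empty:
            raise ValueError(f"anchor structure {anchor!r} is empty in {name} set")
    t = repo[anchor].center_of_mass() - daily[anchor].center_of_mass()
    return RigidTransform(t, np.eye(3), daily.frame_id, repo.frame_id)


def volume_cc(mask: Mask) -> float:
    """Volume of a mask in cm³ (voxel count × voxel volume)."""
    return mask.count * mask.grid.voxel_volume_mm3 / 1000.0
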