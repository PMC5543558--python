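"""Voxel-grid geometry for target structures.

All geometry lives on a physical voxel grid in patient millimetres
(right-handed frame, 0-based indexing, array axes ordered (x, y, z)).
Structures are represented either as planar closed contours (the native
currency of RT structure sets) or as binary occupancy masks on a grid.
The operations here cover the geometric half of composite-volume margin
derivation: rasterization, rigid translation, union of per-fraction
structures, isotropic expansion, and volumetric overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .errors import (
    EmptyCompositeError,
    GridMismatchError,
    ProtocolMixingError,
    UnmappableContourError,
)

PROTOCOLS = ("bone", "soft_tissue")

__all__ = [
    "PROTOCOLS",
    "VoxelGrid",
    "ContourSlice",
    "ContourSet",
    "StructureMask",
    "RegistrationShift",
    "FractionStructure",
    "CompositeStructure",
    "rasterize",
    "apply_shift",
    "make_composite",
    "expand_isotropic",
    "distance_map",
    "overlap_fraction",
    "shift_mask",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Axis-aligned voxel lattice in physical coordinates.

    Parameters
    ----------
    origin
        Physical position (mm) of the centre of voxel (0, 0, 0).
    spacing
        Voxel pitch (mm) per axis; anisotropy (e.g. 2.5 mm slices on a
        1 mm in-plane grid) is allowed.
    dims
        Voxel counts per axis.
    """

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "spacing", tuple(float(v) for v in self.spacing))
        object.__setattr__(self, "dims", tuple(int(v) for v in self.dims))
        if len(self.origin) != 3 or len(self.spacing) != 3 or len(self.dims) != 3:
            raise ValueError("origin, spacing and dims must be 3-vectors")
        if any(not math.isfinite(v) for v in self.origin + self.spacing):
            raise ValueError("grid origin and spacing must be finite")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be > 0, got {self.spacing}")
        if any(d < 1 for d in self.dims):
            raise ValueError(f"all dims must be >= 1, got {self.dims}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def axis_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.dims[axis])

    @property
    def z_positions(self) -> np.ndarray:
        return self.axis_centers(2)

    def nearest_slice(self, z: float) -> int:
        """Index of the grid slice nearest to physical position ``z``.

        Raises
        ------
        UnmappableContourError
            If ``z`` is farther than half a slice spacing from every slice.
        """
        sz = self.spacing[2]
        k = round((z - self.origin[2]) / sz)
        if k < 0 or k >= self.dims[2]:
            raise UnmappableContourError(
                f"contour slice at z={z:.3f} mm lies outside the grid "
                f"(z range {self.origin[2]:.3f}..{self.z_positions[-1]:.3f} mm)"
            )
        # half-spacing tolerance, with a hair of slack for float round-off
        if abs(z - (self.origin[2] + k * sz)) > sz / 2 + 1e-9:
            raise UnmappableContourError(
                f"contour slice at z={z:.3f} mm is farther than half a slice "
                f"spacing ({sz / 2:.3f} mm) from every grid slice"
            )
        return int(k)


@dataclass(frozen=True)
class ContourSlice:
    """Closed planar polygons on one axial plane.

    ``polygons`` are (n, 2) float arrays of in-plane (x, y) vertices in mm;
    the closing edge from last to first vertex is implicit.
    """

    z: float
    polygons: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        polys = []
        for p in self.polygons:
            arr = np.asarray(p, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2:
                raise ValueError("polygon must be an (n, 2) vertex array")
            # drop an explicit closing vertex
            if len(arr) > 1 and np.array_equal(arr[0], arr[-1]):
                arr = arr[:-1]
            if len(arr) < 3:
                raise ValueError("polygon needs at least 3 distinct vertices")
            polys.append(arr)
        object.__setattr__(self, "polygons", tuple(polys))


@dataclass(frozen=True)
class ContourSet:
    """A named structure as a stack of planar contours.

    ``source`` identifies provenance: the literal ``"planning"`` or a
    fraction index.
    """

    label: str
    slices: tuple[ContourSlice, ...]
    source: str | int = "planning"

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("structure label must be non-empty")
        object.__setattr__(self, "slices", tuple(self.slices))

    @property
    def n_polygons(self) -> int:
        return sum(len(s.polygons) for s in self.slices)


@dataclass
class StructureMask:
    """Binary occupancy of a structure on a voxel grid."""

    grid: VoxelGrid
    occupancy: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy)
        if occ.shape != self.grid.dims:
            raise ValueError(
                f"occupancy shape {occ.shape} does not match grid dims {self.grid.dims}"
            )
        if occ.dtype != bool:
            uniq = np.unique(occ)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("occupancy must be strictly binary")
            occ = occ.astype(bool)
        self.occupancy = occ

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.occupancy))

    @property
    def volume_mm3(self) -> float:
        return self.voxel_count * self.grid.voxel_volume

    @property
    def volume_cm3(self) -> float:
        return self.volume_mm3 / 1000.0


@dataclass(frozen=True)
class RegistrationShift:
    """Rigid translation mapping the fraction (CBCT) frame into the planning frame."""

    translation: tuple[float, float, float]
    protocol: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "translation", tuple(float(v) for v in self.translation)
        )
        if len(self.translation) != 3 or any(
            not math.isfinite(v) for v in self.translation
        ):
            raise ValueError("translation must be a finite 3-vector")
        if self.protocol not in PROTOCOLS:
            raise ValueError(
                f"protocol must be one of {PROTOCOLS}, got {self.protocol!r}"
            )


@dataclass(frozen=True)
class FractionStructure:
    """One structure contoured on one treatment fraction, with its registration."""

    contours: ContourSet
    shift: RegistrationShift
    fraction_index: int

    def __post_init__(self) -> None:
        if self.fraction_index < 1:
            raise ValueError("fraction_index is 1-based and must be >= 1")


@dataclass(frozen=True)
class CompositeStructure:
    """Union of registered per-fraction structures — the envelope of observed
    target positions, and the denominator of every overlap measurement."""

    mask: StructureMask
    n_fractions: int
    protocol: str


# ---------------------------------------------------------------------------
# rasterization


def _even_odd_inside(polygon: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Crossing-number (even-odd) inside test of grid points against one polygon.

    ``xs``/``ys`` are the 1-D centre coordinates of the in-plane grid; returns
    a boolean (len(xs), len(ys)) array. Points exactly on an edge follow the
    half-open convention of the ray-cast, which is measure-zero on real data.
    """
    X = xs[:, None]
    Y = ys[None, :]
    inside = np.zeros((len(xs), len(ys)), dtype=bool)
    verts = polygon
    x1, y1 = verts[:, 0], verts[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)
    for ex1, ey1, ex2, ey2 in zip(x1, y1, x2, y2):
        if ey1 == ey2:
            continue
        crosses = (ey1 > Y) != (ey2 > Y)
        x_at = ex1 + (Y - ey1) * (ex2 - ex1) / (ey2 - ey1)
        inside ^= crosses & (X < x_at)
    return inside


def rasterize(contours: ContourSet, grid: VoxelGrid) -> StructureMask:
    """Rasterize planar contours onto a voxel grid.

    A voxel is occupied iff its centre lies inside an odd number of that
    slice's polygons (even-odd rule, so holes and islands behave sensibly).
    Each contour plane is assigned to the nearest grid slice; a plane farther
    than half a slice spacing from every slice raises
    :class:`~compositemargins.errors.UnmappableContourError`.
    """
    occ = np.zeros(grid.dims, dtype=bool)
    xs = grid.axis_centers(0)
    ys = grid.axis_centers(1)
    sx, sy = grid.spacing[0], grid.spacing[1]
    for sl in contours.slices:
        k = grid.nearest_slice(sl.z)
        parity = np.zeros((grid.dims[0], grid.dims[1]), dtype=bool)
        for poly in sl.polygons:
            # restrict the point test to the polygon's bounding box
            xmin, ymin = poly.min(axis=0)
            xmax, ymax = poly.max(axis=0)
            i0 = max(0, int(np.ceil((xmin - grid.origin[0]) / sx)) - 1)
            i1 = min(len(xs), int(np.floor((xmax - grid.origin[0]) / sx)) + 2)
            j0 = max(0, int(np.ceil((ymin - grid.origin[1]) / sy)) - 1)
            j1 = min(len(ys), int(np.floor((ymax - grid.origin[1]) / sy)) + 2)
            if i0 >= i1 or j0 >= j1:
                continue
            parity[i0:i1, j0:j1] ^= _even_odd_inside(poly, xs[i0:i1], ys[j0:j1])
        # distinct contour planes snapped to one slice accumulate by union
        occ[:, :, k] |= parity
    return StructureMask(grid=grid, occupancy=occ, label=contours.label)


def apply_shift(contours: ContourSet, shift: RegistrationShift) -> ContourSet:
    """Translate a contour set rigidly in continuous coordinates.

    Applied *before* rasterization so non-integer shifts stay volume
    preserving; label and topology are untouched.
    """
    dx, dy, dz = shift.translation
    shifted = tuple(
        ContourSlice(
            z=sl.z + dz,
            polygons=tuple(p + np.array([dx, dy]) for p in sl.polygons),
        )
        for sl in contours.slices
    )
    return replace(contours, slices=shifted)


def make_composite(
    fractions: Sequence[FractionStructure], grid: VoxelGrid
) -> CompositeStructure:
    """Voxelwise union of registered per-fraction structures.

    Every fraction's contours are shifted into the planning frame by its
    registration translation, rasterized onto the planning grid, and OR-ed.
    All fractions must share a single match protocol.
    """
    if not fractions:
        raise ValueError("make_composite needs at least one fraction structure")
    protocols = {f.shift.protocol for f in fractions}
    if len(protocols) > 1:
        raise ProtocolMixingError(
            f"fractions mix match protocols {sorted(protocols)}; "
            "build one composite per protocol"
        )
    occ = np.zeros(grid.dims, dtype=bool)
    for f in fractions:
        occ |= rasterize(apply_shift(f.contours, f.shift), grid).occupancy
    mask = StructureMask(grid=grid, occupancy=occ, label=fractions[0].contours.label)
    return CompositeStructure(
        mask=mask, n_fractions=len(fractions), protocol=protocols.pop()
    )


# ---------------------------------------------------------------------------
# expansion and overlap


def distance_map(mask: StructureMask) -> np.ndarray:
    """Euclidean distance (mm) from each voxel centre to the nearest occupied
    voxel centre, respecting anisotropic spacing. Occupied voxels map to 0.

    One distance map answers every margin query on the same structure:
    ``distance_map(m) <= margin`` is exactly the occupancy of
    :func:`expand_isotropic`, which is how the margin sweep amortises its
    expansions.
    """
    if mask.voxel_count == 0:
        return np.full(mask.grid.dims, np.inf)
    return ndimage.distance_transform_edt(
        ~mask.occupancy, sampling=mask.grid.spacing
    )


def expand_isotropic(mask: StructureMask, margin: float) -> StructureMask:
    """Uniform (isotropic) expansion of a binary structure by ``margin`` mm.

    A voxel is occupied in the result iff its Euclidean distance in physical
    units to the nearest occupied input voxel centre is <= margin (closed
    ball). Margin 0 returns the input occupancy unchanged; the result is
    always a superset of the input. Contraction (negative margin) is refused.
    """
    if margin < 0:
        raise ValueError(f"margin must be >= 0 (contraction unsupported), got {margin}")
    if margin == 0:
        return StructureMask(
            grid=mask.grid, occupancy=mask.occupancy.copy(), label=mask.label
        )
    occ = distance_map(mask) <= margin
    return StructureMask(grid=mask.grid, occupancy=occ, label=mask.label)


def shift_mask(mask: StructureMask, translation: Sequence[float]) -> StructureMask:
    """Rigidly translate mask content on its own grid (nearest-voxel).

    Used for fraction structures supplied as voxel masks rather than
    contours; sub-voxel components of the translation are rounded in the
    nearest-neighbour resampling, so prefer shifting contours before
    rasterization when contours are available.
    """
    t = np.asarray(translation, dtype=float)
    if t.shape != (3,) or not np.all(np.isfinite(t)):
        raise ValueError("translation must be a finite 3-vector")
    shift_vox = t / np.asarray(mask.grid.spacing)
    occ = ndimage.shift(
        mask.occupancy.astype(np.uint8), shift_vox, order=0, prefilter=False, cval=0
    ).astype(bool)
    return StructureMask(grid=mask.grid, occupancy=occ, label=mask.label)


def overlap_fraction(ptv: StructureMask, composite: CompositeStructure) -> float:
    """Overlap of a PTV with a composite structure, as % of the composite.

    The denominator is always the composite volume — the quantity of
    interest is how much of the envelope of observed target positions the
    expanded planning structure covers, never the reverse.
    """
    if ptv.grid != composite.mask.grid:
        raise GridMismatchError(
            "PTV and composite are defined on different voxel grids"
        )
    n_comp = composite.mask.voxel_count
    if n_comp == 0:
        raise EmptyCompositeError(
            "composite structure has zero volume; overlap undefined"
        )
    n_inter = int(np.count_nonzero(ptv.occupancy & composite.mask.occupancy))
    return 100.0 * n_inter / n_comp
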