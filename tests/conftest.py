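"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the code paths they check: point-in-polygon
goes through shapely, expansion through an explicit all-pairs distance
scan, union through set arithmetic on brute-force masks.
"""

from __future__ import annotations

import numpy as np
import pytest
import shapely

from compositemargins import (
    CompositeStructure,
    ContourSet,
    ContourSlice,
    StructureMask,
    VoxelGrid,
)


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_points_in_polygons(polygons, xs, ys):
    """Even-odd insideness of grid centres via shapely (XOR across polygons)."""
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    inside = np.zeros(X.shape, dtype=bool)
    for poly in polygons:
        geom = shapely.Polygon(poly)
        inside ^= shapely.contains_xy(geom, X.ravel(), Y.ravel()).reshape(X.shape)
    return inside


def brute_rasterize(contours: ContourSet, grid: VoxelGrid) -> np.ndarray:
    """Exhaustive per-voxel-centre rasterization oracle."""
    occ = np.zeros(grid.dims, dtype=bool)
    xs, ys, zs = (grid.axis_centers(a) for a in range(3))
    for sl in contours.slices:
        k = int(np.argmin(np.abs(zs - sl.z)))
        assert abs(zs[k] - sl.z) <= grid.spacing[2] / 2 + 1e-9
        occ[:, :, k] |= brute_points_in_polygons(sl.polygons, xs, ys)
    return occ


def brute_expand(occ: np.ndarray, spacing, margin: float) -> np.ndarray:
    """Exhaustive closed-ball expansion: every centre within ``margin`` mm of
    any occupied centre (physical anisotropic distance)."""
    spacing = np.asarray(spacing, dtype=float)
    occupied = np.argwhere(occ) * spacing
    if occupied.size == 0:
        return np.zeros_like(occ)
    centers = (
        np.stack(np.meshgrid(*[np.arange(d) for d in occ.shape], indexing="ij"), -1)
        .reshape(-1, 3)
        * spacing
    )
    d2 = ((centers[:, None, :] - occupied[None, :, :]) ** 2).sum(-1)
    return (np.sqrt(d2.min(axis=1)) <= margin).reshape(occ.shape)


def random_polygon(rng: np.random.Generator, center, radius: float) -> np.ndarray:
    """Random star-convex polygon (simple, non-self-intersecting)."""
    n = int(rng.integers(5, 12))
    angles = np.sort(rng.uniform(0, 2 * np.pi, size=n))
    radii = rng.uniform(0.3 * radius, radius, size=n)
    return np.column_stack(
        [center[0] + radii * np.cos(angles), center[1] + radii * np.sin(angles)]
    )


def random_contour_set(
    rng: np.random.Generator, grid: VoxelGrid, label: str = "S"
) -> ContourSet:
    xs, ys, zs = (grid.axis_centers(a) for a in range(3))
    extent = min(xs[-1] - xs[0], ys[-1] - ys[0])
    n_slices = int(rng.integers(1, min(4, grid.dims[2]) + 1))
    ks = rng.choice(grid.dims[2], size=n_slices, replace=False)
    slices = []
    for k in ks:
        n_poly = int(rng.integers(1, 3))
        polys = [
            random_polygon(
                rng,
                center=(
                    rng.uniform(xs[0], xs[-1]),
                    rng.uniform(ys[0], ys[-1]),
                ),
                radius=rng.uniform(0.15, 0.45) * extent,
            )
            for _ in range(n_poly)
        ]
        # sub-voxel z offset still within the half-spacing snap tolerance
        dz = rng.uniform(-0.49, 0.49) * grid.spacing[2]
        slices.append(ContourSlice(z=float(zs[k] + dz), polygons=tuple(polys)))
    slices.sort(key=lambda s: s.z)
    return ContourSet(label=label, slices=tuple(slices))


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def unit_grid() -> VoxelGrid:
    """20^3 grid, 1 mm isotropic, origin at 0."""
    return VoxelGrid(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(20, 20, 20))


@pytest.fixture
def square_contours() -> ContourSet:
    """10 x 10 mm axis-aligned square on one slice of a 1 mm grid.

    Vertices span -0.5..9.5 mm in x and y, so exactly the 100 voxel centres
    at 0..9 mm lie strictly inside.
    """
    square = np.array([[-0.5, -0.5], [9.5, -0.5], [9.5, 9.5], [-0.5, 9.5]])
    return ContourSet(label="SQ", slices=(ContourSlice(z=5.0, polygons=(square,)),))


def make_mask(grid: VoxelGrid, occ: np.ndarray, label: str = "M") -> StructureMask:
    return StructureMask(grid=grid, occupancy=occ.astype(bool), label=label)


def sphere_mask(grid: VoxelGrid, center, radius: float, label="SPH") -> StructureMask:
    """Analytic sphere sampled at voxel centres (independent of rasterize)."""
    coords = [grid.axis_centers(a) for a in range(3)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    c = np.asarray(center, dtype=float)
    occ = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= radius**2
    return StructureMask(grid=grid, occupancy=occ, label=label)


def as_composite(mask: StructureMask, protocol: str = "bone", n: int = 1):
    return CompositeStructure(mask=mask, n_fractions=n, protocol=protocol)
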