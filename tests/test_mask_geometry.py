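"""Geometry unit and property tests: rasterization, shifts, unions,
expansion and overlap, each checked against independent brute force."""

import numpy as np
import pytest

from compositemargins import (
    ContourSet,
    ContourSlice,
    RegistrationShift,
    FractionStructure,
    StructureMask,
    VoxelGrid,
    apply_shift,
    distance_map,
    expand_isotropic,
    make_composite,
    overlap_fraction,
    rasterize,
    shift_mask,
)
from compositemargins.errors import (
    EmptyCompositeError,
    GridMismatchError,
    ProtocolMixingError,
    UnmappableContourError,
)

from conftest import (
    as_composite,
    brute_expand,
    brute_rasterize,
    make_mask,
    random_contour_set,
    sphere_mask,
)


class TestVoxelGrid:
    def test_rejects_nonpositive_spacing_and_dims(self):
        with pytest.raises(ValueError):
            VoxelGrid(origin=(0, 0, 0), spacing=(1, 0, 1), dims=(5, 5, 5))
        with pytest.raises(ValueError):
            VoxelGrid(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(5, 0, 5))

    def test_voxel_volume_anisotropic(self):
        g = VoxelGrid(origin=(0, 0, 0), spacing=(1, 1, 2.5), dims=(4, 4, 4))
        assert g.voxel_volume == 2.5


class TestRasterize:
    def test_aligned_square_occupies_100_voxels(self, unit_grid, square_contours):
        mask = rasterize(square_contours, unit_grid)
        assert mask.voxel_count == 100
        assert mask.occupancy[:, :, 5].sum() == 100

    def test_empty_contour_set_gives_zero_volume(self, unit_grid):
        empty = ContourSet(label="E", slices=())
        assert rasterize(empty, unit_grid).volume_mm3 == 0.0

    def test_circle_matches_exhaustive_center_test(self, unit_grid):
        # radius 7.5 mm circle; oracle: count of centres within the radius
        center = (9.4, 9.7)
        radius = 7.5
        theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        poly = np.column_stack(
            [center[0] + radius * np.cos(theta), center[1] + radius * np.sin(theta)]
        )
        cs = ContourSet(label="C", slices=(ContourSlice(z=3.0, polygons=(poly,)),))
        mask = rasterize(cs, unit_grid)
        xs = unit_grid.axis_centers(0)
        X, Y = np.meshgrid(xs, unit_grid.axis_centers(1), indexing="ij")
        # chord sagitta of the 720-gon is ~0.02 um, so the polygon and the
        # true circle classify centres identically away from a knife edge
        expected = (X - center[0]) ** 2 + (Y - center[1]) ** 2 <= radius**2
        assert mask.voxel_count == int(expected.sum())

    def test_even_odd_rule_carves_holes(self, unit_grid):
        outer = np.array([[-0.5, -0.5], [14.5, -0.5], [14.5, 14.5], [-0.5, 14.5]])
        inner = np.array([[3.5, 3.5], [10.5, 3.5], [10.5, 10.5], [3.5, 10.5]])
        cs = ContourSet(
            label="H", slices=(ContourSlice(z=0.0, polygons=(outer, inner)),)
        )
        mask = rasterize(cs, unit_grid)
        assert mask.voxel_count == 15 * 15 - 7 * 7

    def test_contour_beyond_half_slice_spacing_raises(self, unit_grid):
        sq = np.array([[0, 0], [4, 0], [4, 4], [0, 4]], dtype=float)
        cs = ContourSet(label="S", slices=(ContourSlice(z=25.0, polygons=(sq,)),))
        with pytest.raises(UnmappableContourError, match="25"):
            rasterize(cs, unit_grid)


class TestApplyShift:
    def test_zero_shift_is_identity(self, square_contours):
        shifted = apply_shift(
            square_contours, RegistrationShift((0, 0, 0), "bone")
        )
        for a, b in zip(shifted.slices, square_contours.slices):
            assert a.z == b.z
            assert all(np.array_equal(p, q) for p, q in zip(a.polygons, b.polygons))

    def test_shift_then_inverse_recovers_vertices(self, square_contours):
        fwd = RegistrationShift((3, -2, 0), "bone")
        back = RegistrationShift((-3, 2, 0), "bone")
        round_trip = apply_shift(apply_shift(square_contours, fwd), back)
        for a, b in zip(round_trip.slices, square_contours.slices):
            assert all(
                np.allclose(p, q) for p, q in zip(a.polygons, b.polygons)
            )

    def test_subvoxel_shift_matches_exhaustive_test(self, unit_grid, square_contours):
        # off-lattice shift so no voxel centre sits exactly on an edge (where
        # the half-open ray-cast and a strict inside test may differ)
        shifted = apply_shift(
            square_contours, RegistrationShift((0.45, 0.3, 0), "soft_tissue")
        )
        mask = rasterize(shifted, unit_grid)
        np.testing.assert_array_equal(
            mask.occupancy, brute_rasterize(shifted, unit_grid)
        )

    def test_translation_consistency_whole_voxel_shift(self, square_contours):
        # shifting contours by t equals moving the grid origin by -t
        t = (3.0, -2.0, 1.0)
        g0 = VoxelGrid(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(20, 20, 20))
        g_moved = VoxelGrid(origin=(-3.0, 2.0, -1.0), spacing=(1, 1, 1), dims=(20, 20, 20))
        shifted = apply_shift(square_contours, RegistrationShift(t, "bone"))
        np.testing.assert_array_equal(
            rasterize(shifted, g0).occupancy,
            rasterize(square_contours, g_moved).occupancy,
        )


class TestMakeComposite:
    def _fraction(self, cs, shift, protocol, idx):
        return FractionStructure(
            contours=cs,
            shift=RegistrationShift(shift, protocol),
            fraction_index=idx,
        )

    def test_identical_zero_shift_fractions_idempotent(self, unit_grid, square_contours):
        fracs = [
            self._fraction(square_contours, (0, 0, 0), "bone", i) for i in range(1, 6)
        ]
        comp = make_composite(fracs, unit_grid)
        single = rasterize(square_contours, unit_grid)
        np.testing.assert_array_equal(comp.mask.occupancy, single.occupancy)
        assert comp.n_fractions == 5

    def test_disjoint_structures_add(self, unit_grid):
        tiny = np.array([[-0.4, -0.4], [0.4, -0.4], [0.4, 0.4], [-0.4, 0.4]])
        cs = ContourSet(label="V", slices=(ContourSlice(z=0.0, polygons=(tiny,)),))
        fracs = [
            self._fraction(cs, (0, 0, 0), "bone", 1),
            self._fraction(cs, (5, 0, 0), "bone", 2),
        ]
        comp = make_composite(fracs, unit_grid)
        assert comp.mask.volume_mm3 == 2 * unit_grid.voxel_volume

    def test_mixed_protocols_rejected(self, unit_grid, square_contours):
        fracs = [
            self._fraction(square_contours, (0, 0, 0), "bone", 1),
            self._fraction(square_contours, (1, 0, 0), "soft_tissue", 2),
        ]
        with pytest.raises(ProtocolMixingError):
            make_composite(fracs, unit_grid)

    def test_two_spheres_match_brute_union(self):
        # spheres r=10 mm, centres 5 mm apart, on a 1 mm grid
        g = VoxelGrid(origin=(-15, -15, -15), spacing=(1, 1, 1), dims=(36, 36, 31))
        theta = np.linspace(0, 2 * np.pi, 360, endpoint=False)

        def sphere_cs(cx):
            slices = []
            for z in g.z_positions:
                r2 = 10.0**2 - z**2
                if r2 <= 0.25:
                    continue
                r = np.sqrt(r2)
                poly = np.column_stack(
                    [cx + r * np.cos(theta), r * np.sin(theta)]
                )
                slices.append(ContourSlice(z=float(z), polygons=(poly,)))
            return ContourSet(label="S", slices=tuple(slices))

        fracs = [
            self._fraction(sphere_cs(0.3), (0, 0, 0), "bone", 1),
            self._fraction(sphere_cs(0.3), (5, 0, 0), "bone", 2),
        ]
        comp = make_composite(fracs, g)
        a = brute_rasterize(sphere_cs(0.3), g)
        b = brute_rasterize(
            apply_shift(sphere_cs(0.3), RegistrationShift((5, 0, 0), "bone")), g
        )
        assert comp.mask.voxel_count == int(np.count_nonzero(a | b))

    def test_union_bounds(self, unit_grid):
        rng = np.random.default_rng(7)
        css = [random_contour_set(rng, unit_grid) for _ in range(3)]
        fracs = [
            self._fraction(cs, tuple(rng.uniform(-2, 2, 3)), "bone", i + 1)
            for i, cs in enumerate(css)
        ]
        comp = make_composite(fracs, unit_grid)
        vols = [
            rasterize(apply_shift(f.contours, f.shift), unit_grid).voxel_count
            for f in fracs
        ]
        assert max(vols) <= comp.mask.voxel_count <= sum(vols)


class TestExpandIsotropic:
    def test_zero_margin_is_identity(self, unit_grid):
        rng = np.random.default_rng(1)
        occ = rng.random(unit_grid.dims) < 0.1
        mask = make_mask(unit_grid, occ)
        out = expand_isotropic(mask, 0.0)
        np.testing.assert_array_equal(out.occupancy, occ)

    def test_negative_margin_rejected(self, unit_grid):
        mask = make_mask(unit_grid, np.zeros(unit_grid.dims, bool))
        with pytest.raises(ValueError):
            expand_isotropic(mask, -1.0)

    def test_single_voxel_ball_matches_brute_count(self):
        g = VoxelGrid(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(11, 11, 11))
        occ = np.zeros(g.dims, bool)
        occ[5, 5, 5] = True
        out = expand_isotropic(make_mask(g, occ), 2.5)
        np.testing.assert_array_equal(
            out.occupancy, brute_expand(occ, g.spacing, 2.5)
        )
        # closed ball on the integer lattice: |{v : |v| <= 2.5}| = 81
        assert out.voxel_count == 81

    def test_anisotropic_spacing_respected(self):
        g = VoxelGrid(origin=(0, 0, 0), spacing=(1, 1, 2.5), dims=(9, 9, 9))
        occ = np.zeros(g.dims, bool)
        occ[4, 4, 4] = True
        out = expand_isotropic(make_mask(g, occ), 2.6)
        np.testing.assert_array_equal(
            out.occupancy, brute_expand(occ, g.spacing, 2.6)
        )
        # one slice step costs 2.5 mm, so only +-1 slice is reachable
        assert out.occupancy[:, :, 2].sum() == 0
        assert out.occupancy[4, 4, 3] and out.occupancy[4, 4, 5]

    def test_sphere_expansion_approaches_analytic_volume(self):
        # sphere centred on a voxel corner: the symmetric sampling of the
        # analytic shape (centre-of-voxel placement aligns the boundary with
        # the lattice and exaggerates the half-voxel surface deficit)
        g = VoxelGrid(origin=(-22, -22, -22), spacing=(1, 1, 1), dims=(45, 45, 45))
        sph = sphere_mask(g, (0.5, 0.5, 0.5), 15.0)
        out = expand_isotropic(sph, 5.0)
        analytic = 4.0 / 3.0 * np.pi * 20.0**3
        assert abs(out.volume_mm3 - analytic) / analytic < 0.02

    def test_monotone_in_margin(self, unit_grid):
        rng = np.random.default_rng(3)
        occ = rng.random(unit_grid.dims) < 0.02
        mask = make_mask(unit_grid, occ)
        prev = expand_isotropic(mask, 0.7).occupancy
        for m in (1.3, 2.9, 4.4):
            cur = expand_isotropic(mask, m).occupancy
            assert np.all(prev <= cur)
            prev = cur


class TestOverlapFraction:
    def test_containment_gives_100(self, unit_grid):
        inner = np.zeros(unit_grid.dims, bool)
        inner[8:12, 8:12, 8:12] = True
        outer = np.zeros(unit_grid.dims, bool)
        outer[5:15, 5:15, 5:15] = True
        assert overlap_fraction(
            make_mask(unit_grid, outer), as_composite(make_mask(unit_grid, inner))
        ) == 100.0

    def test_disjoint_gives_0(self, unit_grid):
        a = np.zeros(unit_grid.dims, bool)
        a[:3] = True
        b = np.zeros(unit_grid.dims, bool)
        b[10:] = True
        assert overlap_fraction(
            make_mask(unit_grid, a), as_composite(make_mask(unit_grid, b))
        ) == 0.0

    def test_half_partition_gives_50(self):
        g = VoxelGrid(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(10, 10, 10))
        comp = np.ones(g.dims, bool)
        ptv = np.zeros(g.dims, bool)
        ptv[:5] = True
        assert overlap_fraction(make_mask(g, ptv), as_composite(make_mask(g, comp))) == 50.0

    def test_empty_composite_rejected(self, unit_grid):
        empty = make_mask(unit_grid, np.zeros(unit_grid.dims, bool))
        with pytest.raises(EmptyCompositeError):
            overlap_fraction(empty, as_composite(empty))

    def test_grid_mismatch_rejected(self, unit_grid):
        other = VoxelGrid(origin=(0, 0, 0), spacing=(2, 2, 2), dims=(20, 20, 20))
        a = make_mask(unit_grid, np.ones(unit_grid.dims, bool))
        b = make_mask(other, np.ones(other.dims, bool))
        with pytest.raises(GridMismatchError):
            overlap_fraction(a, as_composite(b))

    def test_denominator_is_composite_not_ptv(self, unit_grid):
        # PTV twice the composite's size but fully covering it: still 100%,
        # and the asymmetry flips to 50% when roles are swapped
        small = np.zeros(unit_grid.dims, bool)
        small[0:5, 0:5, 0:5] = True
        big = np.zeros(unit_grid.dims, bool)
        big[0:10, 0:5, 0:5] = True
        assert overlap_fraction(
            make_mask(unit_grid, big), as_composite(make_mask(unit_grid, small))
        ) == 100.0
        assert overlap_fraction(
            make_mask(unit_grid, small), as_composite(make_mask(unit_grid, big))
        ) == 50.0


class TestShiftMask:
    def test_whole_voxel_shift_translates_content(self, unit_grid):
        occ = np.zeros(unit_grid.dims, bool)
        occ[5, 5, 5] = True
        out = shift_mask(make_mask(unit_grid, occ), (3.0, -2.0, 1.0))
        assert out.occupancy[8, 3, 6]
        assert out.voxel_count == 1

    def test_saturation_at_max_distance(self, unit_grid):
        # beyond the farthest composite voxel the overlap must reach 100%
        rng = np.random.default_rng(11)
        ctv = np.zeros(unit_grid.dims, bool)
        ctv[9:11, 9:11, 9:11] = True
        comp_occ = rng.random(unit_grid.dims) < 0.05
        comp_occ |= ctv
        dist = distance_map(make_mask(unit_grid, ctv))
        worst = dist[comp_occ].max()
        grown = expand_isotropic(make_mask(unit_grid, ctv), worst)
        assert overlap_fraction(
            grown, as_composite(make_mask(unit_grid, comp_occ))
        ) == 100.0
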