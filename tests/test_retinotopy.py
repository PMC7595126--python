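"""Grid construction, stimulus projection geometry, displacement, assignment."""

import numpy as np
import pytest

from maculamap import (DisplacementModel, StimulusSpec, assign_to_square,
                       build_grid8x8, build_vf_grid, deg_to_um,
                       effective_region, hfa_10_2_points,
                       hfa_30_2_paracentral_points, um_to_deg)
from maculamap.retinotopy import GRID_SPAN_UM, disc_polygon


def sig3(x):
    """Round to 3 significant figures."""
    return float(f"{x:.3g}")


class TestDegreeConversion:
    def test_linear_and_invertible(self):
        assert deg_to_um(0.0) == 0.0
        assert deg_to_um(0.43) == pytest.approx(123.195)
        assert um_to_deg(deg_to_um(2.34)) == pytest.approx(2.34, rel=1e-14)

    @pytest.mark.parametrize("name,area_3sf", [
        ("GII", 0.00298), ("GIII", 0.0119), ("GV", 0.191)])
    def test_projected_stimulus_areas(self, name, area_3sf):
        """The single 286.5 μm/deg factor reproduces all three published
        no-allowance stimulus projection areas at 3 s.f."""
        s = StimulusSpec.from_goldmann(name)
        _, area = effective_region(s, with_allowance=False)
        assert sig3(area) == area_3sf

    def test_allowance_inflates_subtense_by_half_degree(self):
        s = StimulusSpec.from_goldmann("GII")
        r_with, _ = effective_region(s, with_allowance=True)
        assert 2 * r_with == pytest.approx(0.215 + 0.5)

    def test_zero_allowance_matches_no_allowance(self):
        s = StimulusSpec.from_goldmann("GIII", allowance_deg=0.0)
        assert effective_region(s, True) == effective_region(s, False)

    def test_area_override(self):
        s = StimulusSpec.from_goldmann("GV")
        _, area = effective_region(s, True, area_override_mm2=0.351)
        assert area == 0.351


class TestGrid8x8:
    def test_square_side_and_count(self):
        grid = build_grid8x8(None)
        assert len(grid.polygons) == 64
        assert grid.square_um == pytest.approx(GRID_SPAN_UM / 8) == 860.0
        for p in grid.polygons:
            assert p.area == pytest.approx(860.0 ** 2, rel=1e-12)

    def test_area_conservation_and_disjointness(self):
        grid = build_grid8x8(None, tilt_deg=7.3)
        total = sum(p.area for p in grid.polygons)
        assert total == pytest.approx(GRID_SPAN_UM ** 2, rel=1e-6)
        from shapely.ops import unary_union
        union = unary_union(grid.polygons)
        assert union.area == pytest.approx(GRID_SPAN_UM ** 2, rel=1e-6)

    def test_tilt_equal_to_scan_tilt_cancels(self, noiseless_map):
        grid = build_grid8x8(noiseless_map)  # default tilt = scan tilt (6°)
        minx, miny, maxx, maxy = grid.polygons[0].bounds
        # axis-aligned square: bounds box area equals polygon area
        assert (maxx - minx) * (maxy - miny) == pytest.approx(860.0 ** 2)

    def test_row_major_from_superior_temporal(self):
        grid = build_grid8x8(None)
        c0 = np.array(grid.polygons[0].centroid.coords[0])
        c63 = np.array(grid.polygons[63].centroid.coords[0])
        assert c0[0] < 0 and c0[1] > 0      # temporal (x<0), superior (y>0)
        assert c63[0] > 0 and c63[1] < 0


class TestDisplacementModel:
    def test_packaged_model_invariants(self):
        m = DisplacementModel.drasdo()
        e = np.linspace(0, 20, 401)
        g = m(e)
        assert (np.diff(g) >= -1e-12).all()
        assert (g >= e - 1e-9).all()
        assert np.allclose(m(e[e >= m.cutoff_deg]), e[e >= m.cutoff_deg])

    def test_identity_model(self):
        m = DisplacementModel.identity()
        assert m(3.7) == pytest.approx(3.7)


class TestVFGrid:
    def test_location_counts(self):
        vf = build_vf_grid(StimulusSpec.from_goldmann("GIII"))
        assert len(vf) == 80
        assert sum(l.source == "10-2" for l in vf.locations) == 68
        assert sum(l.source == "30-2" for l in vf.locations) == 12

    def test_counts_by_brute_force_enumeration(self):
        # independent oracle: enumerate the stated point sets directly
        pts = [(x, y) for x in range(-9, 10, 2) for y in range(-9, 10, 2)
               if x % 2 and y % 2 and np.hypot(x, y) <= 9.3]
        assert len(pts) == 68
        extra = [(sx * a, sy * b) for a, b in [(9, 3), (3, 9), (9, 9)]
                 for sx in (1, -1) for sy in (1, -1)]
        assert len(set(extra)) == 12
        assert not set(extra) & set(pts)
        # the implementation's point sets equal the oracle's
        assert {tuple(q) for q in hfa_10_2_points()} == set(pts)
        assert {tuple(q) for q in hfa_30_2_paracentral_points()} == set(extra)

    def test_no_duplicate_field_positions(self):
        vf = build_vf_grid(StimulusSpec.from_goldmann("GII"))
        assert len({l.field_deg for l in vf.locations}) == 80

    def test_identity_displacement_pure_axis_inversion(self):
        vf = build_vf_grid(StimulusSpec.from_goldmann("GIII"),
                           DisplacementModel.identity())
        for l in vf.locations:
            assert l.retina_deg[0] == pytest.approx(-l.field_deg[0])
            assert l.retina_deg[1] == pytest.approx(-l.field_deg[1])

    def test_displacement_centrifugal_and_identity_beyond_cutoff(self):
        model = DisplacementModel.drasdo()
        vf = build_vf_grid(StimulusSpec.from_goldmann("GIII"), model)
        for l in vf.locations:
            fe = np.hypot(*l.field_deg)
            re = np.hypot(*l.retina_deg)
            assert re >= fe - 1e-9
            if fe >= model.cutoff_deg:  # the four (±9,±9) corners
                assert re == pytest.approx(fe)
        n_beyond = sum(np.hypot(*l.field_deg) >= model.cutoff_deg
                       for l in vf.locations)
        assert n_beyond == 4

    def test_rotated_into_scan_frame(self):
        vf0 = build_vf_grid(StimulusSpec.from_goldmann("GIII"), scan_tilt_deg=0.0)
        vf7 = build_vf_grid(StimulusSpec.from_goldmann("GIII"), scan_tilt_deg=7.0)
        for a, b in zip(vf0.locations, vf7.locations):
            ra = np.hypot(*a.center_um)
            rb = np.hypot(*b.center_um)
            assert ra == pytest.approx(rb, abs=1e-9)  # rotation preserves radius
        # and at least one coordinate actually moved
        assert vf0.locations[0].center_um != vf7.locations[0].center_um


class TestAssignment:
    def test_disc_inside_one_square(self):
        grid = build_grid8x8(None)
        vf = build_vf_grid(StimulusSpec.from_goldmann("GII"))
        # a GII disc (~102 μm radius) centred well inside square row 1 col 2
        loc = vf.locations[0]
        loc.region = disc_polygon((-3440 + 2.5 * 860, 3440 - 1.5 * 860), 102)
        a = assign_to_square(loc, grid)
        assert a.square == 1 * 8 + 2
        assert a.fraction == pytest.approx(1.0)

    def test_four_way_corner_tie_breaks_to_lowest_index_nearest_fovea(self):
        grid = build_grid8x8(None)
        vf = build_vf_grid(StimulusSpec.from_goldmann("GII"))
        loc = vf.locations[0]
        # grid centre = meeting corner of squares 27, 28, 35, 36 (equidistant)
        loc.region = disc_polygon((0.0, 0.0), 100)
        a = assign_to_square(loc, grid)
        assert a.square == 27
        assert a.fraction == pytest.approx(0.25, abs=1e-6)

    def test_zero_overlap_is_unassigned(self):
        grid = build_grid8x8(None)
        vf = build_vf_grid(StimulusSpec.from_goldmann("GII"))
        loc = vf.locations[0]
        loc.region = disc_polygon((6000.0, 6000.0), 100)
        a = assign_to_square(loc, grid)
        assert a.square is None and a.fraction == 0.0

    def test_every_location_assigned_or_unassigned_once(self):
        grid = build_grid8x8(None, tilt_deg=9.0)
        vf = build_vf_grid(StimulusSpec.from_goldmann("GV"))
        squares = [assign_to_square(l, grid).square for l in vf.locations]
        assert len(squares) == 80
        assert all(s is None or 0 <= s < 64 for s in squares)

    @pytest.mark.parametrize("center,radius,tilt", [
        ((430.0, 430.0), 318.0, 0.0),
        ((-1200.0, 700.0), 133.0, 6.6),
        ((2578.5, -2578.5), 318.0, 12.0),
    ])
    def test_overlap_area_matches_monte_carlo(self, center, radius, tilt):
        """Polygon-clipping overlap areas agree with a 10⁶-point
        Monte-Carlo hit-count oracle within 3 standard errors."""
        grid = build_grid8x8(None, tilt_deg=tilt)
        disc = disc_polygon(center, radius)
        rng = np.random.default_rng(42)
        n = 1_000_000
        # sample uniformly in the disc
        u = rng.uniform(0, 1, n)
        th = rng.uniform(0, 2 * np.pi, n)
        pts = np.column_stack([center[0] + radius * np.sqrt(u) * np.cos(th),
                               center[1] + radius * np.sqrt(u) * np.sin(th)])
        disc_area = np.pi * radius ** 2
        import shapely
        for idx in (27, 28, 36, 20):
            exact = disc.intersection(grid.polygons[idx]).area
            hits = shapely.contains_xy(grid.polygons[idx], pts[:, 0], pts[:, 1])
            p = hits.mean()
            mc = p * disc_area
            se = disc_area * np.sqrt(max(p * (1 - p), 1e-12) / n)
            assert abs(mc - exact) <= max(3 * se, 1e-6 * disc_area)
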