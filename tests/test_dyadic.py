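"""Pairwise spatial metrics: overlap, encounter rates, range shifts."""

import numpy as np
import pandas as pd
import pytest
from shapely import affinity
from shapely.geometry import Point, Polygon

from sympatry.dyadic import (
    ShiftEvent,
    classify_driver,
    delta_d,
    driver_proportion,
    encounter_rate,
    overlap_zone,
    proportional_overlap,
    select_shift_events,
)
from sympatry.grids import Grid, Raster
from sympatry.spaceuse import UDGrid
from sympatry.synth.movement import UDSpec

GRID = Grid(0.0, 0.0, 30.0, 200, 200)


def _ud(center, sd, grid=GRID):
    spec = UDSpec("g", 0, "dry", np.array([1.0]), np.array([center]),
                  np.array([sd]), 0.0, 0.3, 10, 0.0, 0.0)
    return UDGrid(grid, spec.density_on(grid))


class TestProportionalOverlap:
    def test_identical_ranges_give_one_both_ways(self):
        disc = Point(0, 0).buffer(100)
        assert proportional_overlap(disc, disc).po == pytest.approx(1.0)

    def test_disjoint_ranges_give_zero(self):
        a = Point(0, 0).buffer(50)
        b = Point(500, 0).buffer(50)
        assert proportional_overlap(a, b).po == 0.0
        assert proportional_overlap(b, a).po == 0.0

    def test_two_disc_lens_closed_form(self):
        # discs radius 2 m, centres 2 m apart: IA = 8 arccos(1/2) - sqrt(12)
        a = Point(0, 0).buffer(2, quad_segs=512)
        b = Point(2, 0).buffer(2, quad_segs=512)
        ia_true = 8 * np.arccos(0.5) - np.sqrt(12.0)
        res_ab = proportional_overlap(a, b)
        res_ba = proportional_overlap(b, a)
        assert res_ab.po == pytest.approx(ia_true / (4 * np.pi), rel=0.005)
        assert res_ba.po == pytest.approx(ia_true / (4 * np.pi), rel=0.005)

    def test_ia_symmetry_po_identity(self):
        a = Point(0, 0).buffer(120)
        b = Point(100, 40).buffer(80)
        r1, r2 = proportional_overlap(a, b), proportional_overlap(b, a)
        assert r1.ia == pytest.approx(r2.ia, rel=1e-6)
        assert r1.po == pytest.approx(r1.ia / r1.hra_focal, abs=1e-9)

    def test_degenerate_focal_rejected(self):
        with pytest.raises(ValueError):
            proportional_overlap(Polygon(), Point(0, 0).buffer(10))


class TestOverlapZone:
    def test_disjoint_zone_is_empty(self):
        z = overlap_zone(Point(0, 0).buffer(10), Point(100, 0).buffer(10))
        assert z.area == 0.0 and np.isnan(z.mean_ndvi)

    def test_nested_zone_equals_inner_range(self):
        inner = Point(0, 0).buffer(50)
        outer = Point(0, 0).buffer(200)
        z = overlap_zone(inner, outer)
        assert z.area == pytest.approx(inner.area, rel=1e-9)

    def test_area_matches_rasterized_intersection(self):
        a = Point(2800, 3000).buffer(600)
        b = Point(3400, 3100).buffer(500)
        z = overlap_zone(a, b)
        X, Y = GRID.meshgrid()
        import shapely

        inside = shapely.contains_xy(a.intersection(b), X.ravel(), Y.ravel())
        raster_area = inside.sum() * GRID.cell_area
        assert abs(z.area - raster_area) <= 2 * GRID.cell_area + 0.02 * z.area

    def test_zonal_ndvi_reported(self):
        r = Raster(GRID, np.full(GRID.shape, 0.42))
        z = overlap_zone(Point(3000, 3000).buffer(400),
                         Point(3200, 3000).buffer(400), r)
        assert z.mean_ndvi == pytest.approx(0.42)


class TestEncounterRate:
    def test_identical_gaussians_closed_form(self):
        # grid in metre units with sub-metre cells around the origin
        grid = Grid(-60.0, -60.0, 0.25, 480, 480)
        ua = _ud((0.0, 0.0), 1.0, grid)
        ub = _ud((0.0, 0.0), 1.0, grid)
        er = encounter_rate(ua, ub, area_scale=1.0)
        assert er.er == pytest.approx(1 / (4 * np.pi), rel=0.01)

    def test_distant_gaussians_vanish(self):
        grid = Grid(-60.0, -60.0, 0.25, 480, 480)
        ua = _ud((-5.0, 0.0), 1.0, grid)
        ub = _ud((5.0, 0.0), 1.0, grid)
        assert encounter_rate(ua, ub).er < 1e-11

    def test_swap_is_bit_identical(self):
        ua = _ud((2800, 3000), 400.0)
        ub = _ud((3300, 3200), 300.0)
        assert encounter_rate(ua, ub).er == encounter_rate(ub, ua).er

    def test_area_scale_linear(self):
        ua = _ud((3000, 3000), 400.0)
        ub = _ud((3300, 3000), 400.0)
        assert encounter_rate(ua, ub, 7.0).er == pytest.approx(
            7 * encounter_rate(ua, ub, 1.0).er
        )

    def test_grid_mismatch_rejected(self):
        other = Grid(0, 0, 60.0, 100, 100)
        with pytest.raises(ValueError):
            encounter_rate(_ud((3000, 3000), 300.0), _ud((3000, 3000), 300.0, other))


class TestDeltaD:
    def test_unchanged_overlap_gives_zero(self):
        z = Point(100, 0).buffer(10)
        assert delta_d((0.0, 0.0), z, z) == pytest.approx(0.0)

    def test_collinear_arithmetic(self):
        z1 = Point(100, 0).buffer(1)
        z2 = Point(300, 0).buffer(1)
        assert delta_d((0.0, 0.0), z1, z2) == pytest.approx(200.0, abs=1e-9)

    def test_rigid_rotation_invariance(self):
        g = Point(50, -20).buffer(30)
        z1 = Point(100, 40).buffer(15)
        z2 = Point(220, 90).buffer(25)
        base = delta_d(g, z1, z2)
        rot = lambda geom: affinity.rotate(geom, 73.0, origin=(17.0, -4.0))
        assert delta_d(rot(g), rot(z1), rot(z2)) == pytest.approx(base, abs=1e-9)

    def test_empty_overlap_rejected(self):
        with pytest.raises(ValueError):
            delta_d((0.0, 0.0), Polygon(), Point(0, 0).buffer(1))


def _brute_force_events(panel, po_low=0.25, po_high=0.45, min_change=5):
    """Independent enumeration used as the oracle for event selection."""
    rec = {
        (r.focal_id, r.neighbour_id, r.period): r for r in panel.itertuples()
    }
    periods = sorted(panel["period"].unique())
    found = set()
    for f, n, t in list(rec):
        for u in periods:
            if u <= t or (f, n, u) not in rec:
                continue
            a, b = rec[(f, n, t)], rec[(f, n, u)]
            if not (a.po < po_low and b.po > po_high):
                continue
            net = (b.focal_size - b.neighbour_size) - (a.focal_size - a.neighbour_size)
            if abs(net) >= min_change:
                found.add((tuple(sorted((f, n))), t, u))
    return found


class TestShiftSelection:
    def _panel(self, rows):
        return pd.DataFrame(
            rows,
            columns=["focal_id", "neighbour_id", "period", "po",
                     "focal_size", "neighbour_size"],
        )

    def test_boundary_passing_event_selected(self):
        rows = [
            ("a", "b", "1", 0.24, 10, 10), ("b", "a", "1", 0.20, 10, 10),
            ("a", "b", "2", 0.46, 15, 10), ("b", "a", "2", 0.30, 10, 15),
        ]
        events = select_shift_events(self._panel(rows))
        assert len(events) == 1
        assert events[0].larger_becoming == "a"

    def test_strict_threshold_excludes_exact_quarter(self):
        rows = [
            ("a", "b", "1", 0.25, 10, 10), ("b", "a", "1", 0.25, 10, 10),
            ("a", "b", "2", 0.46, 15, 10), ("b", "a", "2", 0.46, 10, 15),
        ]
        assert select_shift_events(self._panel(rows)) == []

    def test_small_size_change_excluded(self):
        rows = [
            ("a", "b", "1", 0.10, 10, 10), ("b", "a", "1", 0.10, 10, 10),
            ("a", "b", "2", 0.50, 14, 10), ("b", "a", "2", 0.50, 10, 14),
        ]
        assert select_shift_events(self._panel(rows)) == []

    def test_matches_brute_force_on_random_panel(self, rng):
        groups = [f"g{i}" for i in range(10)]
        periods = [f"{t}" for t in range(7)]
        rows = []
        sizes = {
            (g, t): int(rng.integers(5, 40)) for g in groups for t in periods
        }
        for t in periods:
            for f in groups:
                for n in groups:
                    if f == n:
                        continue
                    rows.append(
                        (f, n, t, float(rng.uniform(0, 0.6)), sizes[(f, t)],
                         sizes[(n, t)])
                    )
        panel = self._panel(rows)
        assert len(panel) >= 500 // 2 * 2
        got = {
            (tuple(sorted((e.focal_id, e.neighbour_id))), e.period_t, e.period_ti)
            for e in select_shift_events(panel)
        }
        assert got == _brute_force_events(panel)


class TestDriverClassification:
    def _event(self, db, ds):
        return ShiftEvent("a~b", "a", "b", "1", "2", 0.1, 0.5, 6, "a",
                         delta_d_bigger=db, delta_d_smaller=ds)

    def test_magnitude_comparison(self):
        assert classify_driver(self._event(-500.0, -20.0)) == "became_larger"
        assert classify_driver(self._event(10.0, -400.0)) == "became_smaller"

    def test_exact_tie_is_indeterminate(self):
        assert classify_driver(self._event(300.0, -300.0)) == "indeterminate"

    def test_unset_deltas_rejected(self):
        with pytest.raises(ValueError):
            classify_driver(ShiftEvent("a~b", "a", "b", "1", "2", 0.1, 0.5, 6, "a"))

    def test_proportion_and_ci(self):
        events = [self._event(-500, -20) for _ in range(8)]
        events += [self._event(5, -400) for _ in range(2)]
        for e in events:
            classify_driver(e)
        prop, (lo, hi), n = driver_proportion(events)
        assert (prop, n) == (0.8, 10)
        assert lo < 0.8 < hi

    def test_all_indeterminate_rejected(self):
        e = self._event(100.0, -100.0)
        classify_driver(e)
        with pytest.raises(ValueError):
            driver_proportion([e])
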