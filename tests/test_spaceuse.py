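"""UD estimation, home-range contours, path length, revisitation."""

import numpy as np
import pytest

from sympatry.grids import Grid
from sympatry.spaceuse import (
    UDGrid,
    daily_path_length,
    fit_ud,
    hdr_threshold,
    hr_contour,
    revisitation_rate,
)
from sympatry.synth.movement import CHI2_95, UDSpec, simulate_ou

GRID = Grid(0.0, 0.0, 30.0, 200, 200)


def _gaussian_points(rng, n=100_000, sd=300.0, center=(3000.0, 3000.0)):
    return rng.normal(center, sd, size=(n, 2))


def _analytic_ud(sd=300.0, center=(3000.0, 3000.0), grid=GRID):
    spec = UDSpec("g", 0, "dry", np.array([1.0]), np.array([center]),
                  np.array([sd]), 0.0, 0.3, 10, 0.0, 0.0)
    return UDGrid(grid, spec.density_on(grid))


class TestFitUD:
    def test_normalization_and_mean_recovery(self, rng):
        ud = fit_ud(_gaussian_points(rng), GRID)
        assert ud.integral == pytest.approx(1.0, abs=1e-6)
        mx, my = ud.mean()
        assert abs(mx - 3000) / 3000 < 0.02 and abs(my - 3000) / 3000 < 0.02

    def test_contour_area_matches_gaussian_ellipse(self, rng):
        ud = fit_ud(_gaussian_points(rng), GRID)
        hr = hr_contour(ud, 0.95)
        analytic = np.pi * 300.0**2 * CHI2_95
        assert abs(hr.area - analytic) / analytic < 0.10

    def test_translation_equivariance(self, rng):
        pts = _gaussian_points(rng, n=5000)
        shift = np.array([600.0, -300.0])
        grid2 = Grid(GRID.x0 + shift[0], GRID.y0 + shift[1], GRID.cell, GRID.nx, GRID.ny)
        ud1 = fit_ud(pts, GRID, bandwidth=(100.0, 100.0))
        ud2 = fit_ud(pts + shift, grid2, bandwidth=(100.0, 100.0))
        np.testing.assert_allclose(ud1.density, ud2.density, rtol=1e-12)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            fit_ud(np.tile([1000.0, 1000.0], (50, 1)), GRID)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_ud(rng.normal(3000, 100, (10, 2)), GRID)


class TestContours:
    def test_gaussian_95_contour_within_5_percent(self):
        ud = _analytic_ud()
        hr = hr_contour(ud, 0.95)
        analytic = np.pi * 300.0**2 * CHI2_95
        assert abs(hr.area - analytic) / analytic < 0.05

    def test_nestedness(self):
        ud = _analytic_ud()
        assert hr_contour(ud, 0.98).area >= hr_contour(ud, 0.95).area

    def test_uniform_ud_contour_is_level_fraction(self):
        grid = Grid(0, 0, 10.0, 100, 100)
        dens = np.zeros((100, 100))
        dens[20:80, 20:80] = 1.0
        dens /= dens.sum() * grid.cell_area
        ud = UDGrid(grid, dens)
        hr = hr_contour(ud, 0.5)
        rect_area = 60 * 60 * grid.cell_area
        # within one cell ring of the rectangle's half-mass area
        assert abs(hr.area - 0.5 * rect_area) <= 61 * grid.cell_area

    def test_threshold_equals_sorted_cell_oracle(self, rng):
        dens = rng.gamma(0.5, size=(50, 50))
        cell_area = 25.0
        dens /= dens.sum() * cell_area
        got = hdr_threshold(dens, cell_area, 0.7)
        # independent brute force: accumulate sorted cells until mass reached
        flat = np.sort(dens.ravel())[::-1]
        acc, k = 0.0, 0
        while acc < 0.7:
            acc += flat[k] * cell_area
            k += 1
        assert got == flat[k - 1]

    def test_polygon_area_close_to_cell_mass_area(self):
        ud = _analytic_ud()
        hr = hr_contour(ud, 0.95)
        assert abs(hr.geometry.area - hr.area) / hr.area < 0.05

    def test_unreachable_level_rejected(self):
        grid = Grid(0, 0, 30.0, 40, 40)
        ud = _analytic_ud(sd=2000.0, center=(600, 600), grid=grid)
        # mass renormalized on grid so reachable; force failure via raw density
        dens = ud.density * 0.5
        with pytest.raises(ValueError):
            hdr_threshold(dens, grid.cell_area, 0.95)

    def test_bootstrap_se_positive(self, rng):
        pts = _gaussian_points(rng, n=2000)
        ud = fit_ud(pts, GRID)
        hr = hr_contour(ud, 0.95, points=pts, n_boot=8, seed=1)
        assert hr.area_se > 0


class TestDailyPathLength:
    def test_constant_speed_identity(self):
        t = np.arange(0, 11 * 3600 + 1, 30.0)
        xy = np.column_stack([t, np.zeros_like(t)])
        pl = daily_path_length(t, xy)
        assert pl.length == pytest.approx(39_600.0, rel=0.01)
        assert pl.qc_pass

    def test_stationary_points_give_zero(self):
        t = np.arange(0, 12 * 3600, 60.0)
        xy = np.full((len(t), 2), 5.0)
        assert daily_path_length(t, xy).length == 0.0

    def test_short_day_flagged_not_rejected(self):
        t = np.arange(0, 2 * 3600, 60.0)
        xy = np.column_stack([t, t])
        assert not daily_path_length(t, xy).qc_pass

    def test_subsampling_a_smooth_path_changes_little(self):
        # smooth sinusoidal day path: curvature scale far above 5-min chords
        t = np.arange(0, 12 * 3600 + 1, 30.0)
        xy = np.column_stack([0.4 * t, 500.0 * np.sin(2 * np.pi * t / 7200.0)])
        full = daily_path_length(t, xy, n_boot=0)
        sub = daily_path_length(t[::10], xy[::10], n_boot=0)
        assert abs(sub.length - full.length) / full.length < 0.10

    def test_duplicate_timestamps_dropped(self):
        t = np.array([0.0, 0.0, 60.0, 120.0])
        xy = np.array([[0, 0], [5, 5], [60, 0], [120, 0]], dtype=float)
        pl = daily_path_length(t, xy)
        assert pl.duration_hours == pytest.approx(120 / 3600)


class TestRevisitation:
    def test_linear_in_radius(self):
        ud = _analytic_ud()
        r1 = revisitation_rate(ud, mean_speed=0.3, radius=25.0)
        r2 = revisitation_rate(ud, mean_speed=0.3, radius=50.0)
        assert r2.rate == pytest.approx(2 * r1.rate)

    def test_uniform_ud_closed_form(self):
        grid = Grid(0, 0, 10.0, 100, 100)
        dens = np.ones((100, 100))
        dens /= dens.sum() * grid.cell_area
        ud = UDGrid(grid, dens)
        area = 1000.0 * 1000.0
        got = revisitation_rate(ud, mean_speed=0.5, radius=30.0)
        assert got.rate == pytest.approx(30.0 * 0.5 / area, rel=1e-9)

    def test_gaussian_self_overlap_closed_form(self):
        ud = _analytic_ud()
        got = revisitation_rate(ud, mean_speed=1.0, radius=1.0)
        assert got.rate == pytest.approx(1 / (4 * np.pi * 300.0**2), rel=0.01)

    def test_invalid_inputs_rejected(self):
        ud = _analytic_ud()
        with pytest.raises(ValueError):
            revisitation_rate(ud, mean_speed=0.0)
        with pytest.raises(ValueError):
            revisitation_rate(ud, mean_speed=1.0, radius=-1.0)
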