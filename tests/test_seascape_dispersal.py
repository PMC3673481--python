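"""Seascape generation, marine distances, advection and release scheme."""

from __future__ import annotations

import heapq

import numpy as np
import pytest
from scipy import ndimage

from seapop.dispersal import (
    ReleaseScheme,
    VelocityField,
    advect,
    advect_many,
    run_releases,
    velocity_at,
)
from seapop.seascape import (
    SHALLOW_CUTOFF_M,
    Seascape,
    build_seascape,
    make_environment,
    marine_distance,
    marine_distance_matrix,
    place_sites,
)


class TestBuildSeascape:
    def test_discrete_divergence_is_zero(self, basin):
        sea, field = basin
        for k in (0, len(field.times) // 2):
            u, v = field.u[k], field.v[k]
            div = np.zeros_like(u)
            div[1:-1, 1:-1] = (u[1:-1, 2:] - u[1:-1, :-2]) / 2 + (
                v[2:, 1:-1] - v[:-2, 1:-1]
            ) / 2
            max_speed = np.sqrt(u**2 + v**2).max()
            assert np.abs(div).max() < 1e-10 * max_speed

    def test_velocity_zero_on_land(self, basin):
        sea, field = basin
        assert np.abs(field.u[:, sea.land_mask]).max() == 0.0
        assert np.abs(field.v[:, sea.land_mask]).max() == 0.0

    def test_seed_determinism(self):
        s1, f1 = build_seascape(nx=30, ny=20, seed=7, span_days=2)
        s2, f2 = build_seascape(nx=30, ny=20, seed=7, span_days=2)
        np.testing.assert_array_equal(s1.land_mask, s2.land_mask)
        np.testing.assert_array_equal(f1.u, f2.u)

    def test_coastal_band_nonempty_and_connected(self, basin):
        sea, _ = basin
        shallow = sea.water_mask & (np.nan_to_num(sea.depth, nan=np.inf) <= SHALLOW_CUTOFF_M)
        assert shallow.sum() > 0
        # the shallow band forms one 8-connected ring along the shore
        lab, n = ndimage.label(shallow, structure=np.ones((3, 3)))
        assert n == 1

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError, match="grid too small"):
            build_seascape(nx=4, ny=4)


class TestPlaceSites:
    def test_fifteen_sites_seventy_five_distinct_cells(self, basin, placement):
        sea, _ = basin
        assert len(placement.labels) == 15
        cells = placement.all_release_cells()
        assert len(cells) == 75
        assert len(set(cells.tolist())) == 75

    def test_release_cells_are_shallow(self, basin, placement):
        sea, _ = basin
        depth = sea.depth.ravel()[placement.all_release_cells()]
        assert np.all(depth <= SHALLOW_CUTOFF_M)

    def test_single_site_allowed(self, basin):
        sea, _ = basin
        pl = place_sites(sea, 1, seed=0)
        assert len(pl.labels) == 1

    def test_too_many_sites_rejected(self, basin):
        sea, _ = basin
        with pytest.raises(ValueError):
            place_sites(sea, 10_000, seed=0)


def dijkstra_oracle(mask: np.ndarray, start: tuple, end: tuple, cell: float) -> float:
    """Plain heap Dijkstra over an 8-connected water mask (True = water)."""
    ny, nx = mask.shape
    dist = {start: 0.0}
    heap = [(0.0, start)]
    while heap:
        d, (y, x) = heapq.heappop(heap)
        if (y, x) == end:
            return d
        if d > dist.get((y, x), np.inf):
            continue
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dy == dx == 0:
                    continue
                ny2, nx2 = y + dy, x + dx
                if 0 <= ny2 < ny and 0 <= nx2 < nx and mask[ny2, nx2]:
                    w = cell * (np.sqrt(2) if dy and dx else 1.0)
                    if d + w < dist.get((ny2, nx2), np.inf):
                        dist[(ny2, nx2)] = d + w
                        heapq.heappush(heap, (d + w, (ny2, nx2)))
    return np.inf


class TestMarineDistance:
    def make_sea(self, water: np.ndarray, cell=2.0) -> Seascape:
        depth = np.where(water, 5.0, np.nan)
        entrance = int(np.flatnonzero(water.ravel())[0])
        return Seascape(water.shape[1], water.shape[0], cell, ~water, depth, entrance)

    def test_self_distance_zero(self, basin):
        sea, _ = basin
        c = int(sea.shallow_cells()[0])
        assert marine_distance(sea, c, c) == 0.0

    def test_straight_line_of_open_water(self):
        water = np.ones((3, 6), dtype=bool)
        sea = self.make_sea(water)
        a, b = 1 * 6 + 0, 1 * 6 + 5
        assert marine_distance(sea, a, b) == pytest.approx(5 * 2.0)

    def test_path_around_land_spit_matches_dijkstra(self):
        water = np.ones((10, 10), dtype=bool)
        water[0:7, 5] = False  # vertical spit
        sea = self.make_sea(water, cell=1.0)
        a = 2 * 10 + 2
        b = 2 * 10 + 8
        d = marine_distance(sea, a, b)
        oracle = dijkstra_oracle(water, (2, 2), (2, 8), 1.0)
        assert d == pytest.approx(oracle)
        assert d > 6.0  # longer than the straight line

    def test_disconnected_cells_are_infinite(self):
        water = np.ones((4, 5), dtype=bool)
        water[:, 2] = False
        sea = self.make_sea(water)
        assert np.isinf(marine_distance(sea, 0, 4))

    def test_symmetry_and_triangle_inequality(self, basin):
        sea, _ = basin
        cells = sea.shallow_cells()[[0, 10, 30]]
        D = marine_distance_matrix(sea, cells)
        assert np.allclose(D, D.T)
        assert D[0, 2] <= D[0, 1] + D[1, 2] + 1e-9


class TestEnvironment:
    def test_entrance_site_has_maximum_salinity(self, basin, placement, environment):
        assert environment["salinity_april"].idxmax() == environment[
            "distance_to_entrance"
        ].idxmin()

    def test_zero_jitter_makes_spawning_equal_april(self, basin, placement):
        sea, _ = basin
        env = make_environment(sea, placement, spawning_jitter=0.0, seed=4)
        np.testing.assert_allclose(env.salinity_april, env.salinity_spawning)
        np.testing.assert_allclose(env.temperature_april, env.temperature_spawning)

    def test_salinity_rank_anticorrelates_with_entrance_distance(self, environment):
        from scipy.stats import spearmanr

        rho = spearmanr(
            environment.salinity_april, environment.distance_to_entrance
        ).statistic
        assert rho == pytest.approx(-1.0)


class TestVelocityInterpolation:
    def make_uniform_field(self, value=(0.1, 0.0), nt=3):
        land = np.zeros((8, 8), dtype=bool)
        u = np.full((nt, 8, 8), value[0])
        v = np.full((nt, 8, 8), value[1])
        return VelocityField(u, v, np.arange(nt) * 6.0, 10.0, land)

    def test_node_snapshot_identity(self, basin):
        _, field = basin
        iy, ix, k = 20, 30, 4
        x = (ix + 0.5) * field.cell_size
        y = (iy + 0.5) * field.cell_size
        u, v = velocity_at(field, x, y, float(field.times[k]))
        assert u == pytest.approx(field.u[k, iy, ix], abs=1e-14)
        assert v == pytest.approx(field.v[k, iy, ix], abs=1e-14)

    def test_uniform_field_everywhere(self):
        field = self.make_uniform_field()
        u, v = velocity_at(field, 13.7, 55.2, 3.0)
        assert u == pytest.approx(0.1)
        assert v == pytest.approx(0.0)

    def test_linear_in_time_midpoint(self):
        land = np.zeros((8, 8), dtype=bool)
        u = np.zeros((2, 8, 8))
        u[1] = 1.0
        field = VelocityField(u, np.zeros_like(u), np.array([0.0, 6.0]), 10.0, land)
        val, _ = velocity_at(field, 40.0, 40.0, 3.0)
        assert val == pytest.approx(0.5)

    def test_time_outside_span_rejected(self):
        field = self.make_uniform_field()
        with pytest.raises(ValueError, match="outside"):
            velocity_at(field, 10.0, 10.0, 1e4)


class TestAdvection:
    def test_zero_velocity_stays_put(self):
        land = np.zeros((8, 8), dtype=bool)
        field = VelocityField(
            np.zeros((2, 8, 8)), np.zeros((2, 8, 8)), np.array([0.0, 600.0]), 10.0, land
        )
        end, lost = advect(field, (35.0, 35.0), 0.0, 21.0, 1.0)
        assert not lost
        assert end == pytest.approx((35.0, 35.0))

    def test_constant_field_displacement_exact(self):
        land = np.zeros((40, 80), dtype=bool)
        u = np.full((2, 40, 80), 0.1)
        field = VelocityField(u, np.zeros_like(u), np.array([0.0, 21 * 24.0]), 10.0, land)
        start = (50.0, 200.0)
        end, lost = advect(field, start, 0.0, 21.0, 1.0)
        assert not lost
        expected_km = 0.1 * 21 * 86400 / 1000
        assert end[0] - start[0] == pytest.approx(expected_km, rel=1e-12)
        assert end[1] == pytest.approx(start[1], abs=1e-12)

    def _rotation_field(self, omega=1e-6, n=41, cell=5.0, span_h=22 * 24.0):
        """Solid-body rotation about the domain centre (omega in 1/s)."""
        land = np.zeros((n, n), dtype=bool)
        c = n * cell / 2
        xs = (np.arange(n) + 0.5) * cell
        X, Y = np.meshgrid(xs, xs)
        # u = -omega (y - c), v = omega (x - c); km * 1/s * 1000 -> m/s
        u = -omega * (Y - c) * 1000
        v = omega * (X - c) * 1000
        times = np.array([0.0, span_h])
        return VelocityField(np.stack([u, u]), np.stack([v, v]), times, cell, land), c

    def test_solid_body_rotation_matches_analytic_orbit(self):
        omega = 2e-6  # rad/s
        field, c = self._rotation_field(omega=omega)
        r0 = 30.0
        start = (c + r0, c)
        end, lost = advect(field, start, 0.0, 21.0, 1.0)
        assert not lost
        t = 21 * 86400
        expected = (c + r0 * np.cos(omega * t), c + r0 * np.sin(omega * t))
        r_end = np.hypot(end[0] - c, end[1] - c)
        assert abs(r_end - r0) / r0 < 1e-6
        assert abs(end[0] - expected[0]) / r0 < 1e-5
        assert abs(end[1] - expected[1]) / r0 < 1e-5

    def test_dt_convergence_on_gyre_field(self, basin):
        sea, field = basin
        cells = sea.shallow_cells()[::20][:10]
        xy = sea.cell_xy(cells)
        end2, _ = advect_many(field, xy, 0.0, 21.0, 2.0)
        end1, _ = advect_many(field, xy, 0.0, 21.0, 1.0)
        path_len = 0.12 * 3.6 * 24 * 21  # generous upper bound, km
        assert np.linalg.norm(end2 - end1, axis=1).max() < 0.01 * path_len

    def test_invalid_dt_rejected(self, basin):
        _, field = basin
        with pytest.raises(ValueError, match="dt"):
            advect(field, (100.0, 100.0), 0.0, 1.0, -1.0)


class TestReleaseScheme:
    def test_paper_scale_trajectory_counts(self):
        scheme = ReleaseScheme()
        assert scheme.trajectories_per_cell == 140 * 25 * 25 == 87_500
        assert scheme.total_trajectories(5168) == 452_200_000

    def test_single_release_single_particle(self, basin):
        sea, field = basin
        scheme = ReleaseScheme(
            particles_per_cell=1, releases_per_year=1, n_years=1,
            duration_days=1.0, dt_hours=2.0, spring_window=(0.0, 1.0),
        )
        cell = sea.shallow_cells()[[3]]
        traj = run_releases(field, sea, scheme, cell, seed=1)
        assert traj.n == 1

    def test_no_trajectory_ends_on_land_and_reproducible(self, basin):
        sea, field = basin
        scheme = ReleaseScheme(
            particles_per_cell=5, releases_per_year=2, n_years=1,
            duration_days=7.0, dt_hours=2.0, spring_window=(0.0, 10.0),
        )
        cells = sea.shallow_cells()[:30]
        t1 = run_releases(field, sea, scheme, cells, seed=9)
        t2 = run_releases(field, sea, scheme, cells, seed=9)
        ended = t1.end_cell[t1.end_cell >= 0]
        assert not sea.land_mask.ravel()[ended].any()
        np.testing.assert_array_equal(t1.end_cell, t2.end_cell)
        np.testing.assert_allclose(t1.end_x, t2.end_x)

    def test_duration_must_divide_dt(self):
        with pytest.raises(ValueError, match="divisible"):
            ReleaseScheme(duration_days=1.0, dt_hours=5.0)
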