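"""Lagrangian transport: advection/diffusion kinematics, gridding,
percentiles, interpolation, hulls and ensemble behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import ConvexHull

from spillsim import environment as env
from spillsim import transport as tr
from spillsim.errors import DegenerateGeometryError, OutsideDomainError
from spillsim.grids import GridSpec, LandMask, metres_per_degree


class TestAdvectStep:
    def test_pure_current_displacement(self):
        # 0.5 m/s east over 1 h = 1,800 m
        lon, lat = tr.advect_step(42.0, 15.0, 0.5, 0.0, 0.0, 0.0, 0.0, 3600.0)
        _, m_lon = metres_per_degree(15.0)
        assert np.isclose((lon - 42.0) * m_lon, 1800.0)
        assert lat == 15.0

    def test_windage_displacement(self):
        # 3% of a 10 m/s northward wind over 1 h = 1,080 m
        lon, lat = tr.advect_step(42.0, 15.0, 0.0, 0.0, 0.0, 10.0, 0.03, 3600.0)
        m_lat, _ = metres_per_degree(15.0)
        assert np.isclose((lat - 15.0) * m_lat, 1080.0)
        assert lon == 42.0

    def test_no_forcing_is_identity(self):
        lon, lat = tr.advect_step(42.0, 15.0, 0.0, 0.0, 0.0, 0.0, 0.02, 3600.0)
        assert (lon, lat) == (42.0, 15.0)


class TestDiffuseStep:
    def test_zero_diffusivity_is_identity(self, rng):
        lon, lat = tr.diffuse_step(np.full(10, 42.0), np.full(10, 15.0), 0.0, 600.0, rng)
        assert np.all(lon == 42.0) and np.all(lat == 15.0)

    def test_fixed_seed_reproducible(self):
        a = tr.diffuse_step(42.0, 15.0, 10.0, 600.0, np.random.default_rng(3))
        b = tr.diffuse_step(42.0, 15.0, 10.0, 600.0, np.random.default_rng(3))
        assert a == b

    def test_variance_matches_2dt(self):
        # Monte Carlo vs the analytic per-axis variance 2 D dt
        n = 100_000
        rng = np.random.default_rng(7)
        lon, lat = tr.diffuse_step(
            np.full(n, 42.0), np.full(n, 15.0), 10.0, 600.0, rng
        )
        m_lat, m_lon = metres_per_degree(15.0)
        var_x = np.var((lon - 42.0) * m_lon)
        var_y = np.var((lat - 15.0) * m_lat)
        assert abs(var_x / 12_000.0 - 1) < 0.02
        assert abs(var_y / 12_000.0 - 1) < 0.02


class TestGridConcentration:
    def test_single_particle_single_cell(self):
        f = tr.grid_concentration([(np.array([15.0]), np.array([42.0]), np.array([3.5]))], 3)
        assert f.cells[(15000, 42000)] == 3.5

    def test_mean_across_two_simulations(self):
        snaps = [
            (np.array([15.0]), np.array([42.0]), np.array([2.0])),
            (np.array([15.0]), np.array([42.0]), np.array([4.0])),
        ]
        f = tr.grid_concentration(snaps, 3)
        assert f.cells[(15000, 42000)] == 3.0

    def test_matches_bruteforce_on_random_simulations(self, rng):
        # oracle: dict accumulation with python round-half-even keys
        n_sims = 100
        snaps = []
        expected: dict = {}
        for _ in range(n_sims):
            n = rng.integers(1, 20)
            lats = rng.uniform(14.0, 14.05, n)
            lons = rng.uniform(42.0, 42.05, n)
            vals = rng.uniform(0, 1, n)
            snaps.append((lats, lons, vals))
            for la, lo, v in zip(lats, lons, vals):
                key = (int(np.rint(la * 1000)), int(np.rint(lo * 1000)))
                expected[key] = expected.get(key, 0.0) + v
        f = tr.grid_concentration(snaps, 3)
        assert set(f.cells) == set(expected)
        for k, v in expected.items():
            assert np.isclose(f.cells[k], v / n_sims)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tr.grid_concentration([], 3)


class TestPercentileTransform:
    def test_four_distinct_values(self):
        cells = {(0, i): float(v) for i, v in enumerate([1, 2, 3, 4])}
        p = tr.SurfaceConcentrationField(cells, 3, 1).percentile_transform()
        assert sorted(p.cells.values()) == [25.0, 50.0, 75.0, 100.0]

    def test_ties_share_highest_rank(self):
        cells = {(0, 0): 2.0, (0, 1): 2.0, (0, 2): 2.0}
        p = tr.SurfaceConcentrationField(cells, 3, 1).percentile_transform()
        assert all(v == 100.0 for v in p.cells.values())

    @given(scale=st.floats(min_value=0.1, max_value=1e4))
    @settings(deadline=None, max_examples=25)
    def test_invariant_under_monotone_rescaling(self, scale):
        cells = {(0, 0): 0.5, (0, 1): 1.0, (1, 0): 7.0, (1, 1): 2.5, (2, 2): 0.1}
        base = tr.SurfaceConcentrationField(cells, 3, 1).percentile_transform()
        scaled = tr.SurfaceConcentrationField(
            {k: v * scale for k, v in cells.items()}, 3, 1
        ).percentile_transform()
        assert base.cells == scaled.cells


class TestBilinearInterpolation:
    def field(self):
        # 2x2 block of cells at 0.001-degree spacing
        return tr.SurfaceConcentrationField(
            {(15000, 42000): 0.0, (15000, 42001): 0.0,
             (15001, 42000): 10.0, (15001, 42001): 10.0},
            3, 1,
        )

    def test_cell_centre_returns_cell_value(self):
        assert self.field().interpolate(42.000, 15.001) == 10.0

    def test_midpoint_of_equal_cells(self):
        assert np.isclose(self.field().interpolate(42.0005, 15.001), 10.0)

    def test_centroid_of_four_cells(self):
        assert np.isclose(self.field().interpolate(42.0005, 15.0005), 5.0)

    def test_outside_domain_raises(self):
        with pytest.raises(OutsideDomainError):
            self.field().interpolate(43.0, 15.0)


class TestUncertaintyRegion:
    def test_unit_square_hull(self, rng):
        corners = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        interior = rng.uniform(0.2, 0.8, size=(50, 2))
        pts = np.vstack([corners, interior])
        region = tr.uncertainty_region(pts[:, 0], pts[:, 1])
        assert np.isclose(region.area, 1.0)
        assert region.contains_all(pts[:, 0], pts[:, 1])

    def test_hull_area_matches_scipy_oracle(self, rng):
        for _ in range(10):
            pts = rng.normal(size=(40, 2))
            region = tr.uncertainty_region(pts[:, 0], pts[:, 1])
            oracle = ConvexHull(pts)
            assert np.isclose(region.area, oracle.volume)  # 2-D "volume" is area
            assert region.contains_all(pts[:, 0], pts[:, 1])

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            tr.uncertainty_region([0.0, 1.0], [0.0, 1.0])
        with pytest.raises(DegenerateGeometryError):
            tr.uncertainty_region([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])  # collinear


def channel_setup(current, wind=(0.0, 0.0), cell=0.5):
    grid = GridSpec(
        lat_min=12.0, lat_max=18.0, lon_min=39.0, lon_max=45.0, cell_size=cell,
        t_start="2020-06-01", t_end="2020-06-30", t_step_h=3.0,
    )
    fields = env.constant_fields(grid, current=current, wind=wind)
    mask = LandMask.channel(grid, west_lon=40.0, east_lon=43.0)
    return grid, fields, mask


class TestRunSimulation:
    def config(self, **kw):
        defaults = dict(
            n_particles=40, n_simulations=1, horizon_days=21.0,
            release_duration_h=24.0, dt_minutes=60.0, diffusivity=0.0,
            concentration_decimals=2, seed=1,
        )
        defaults.update(kw)
        return tr.TrajectoryConfig(**defaults)

    def test_uniform_eastward_current_beaches_east_coast(self):
        _, fields, mask = channel_setup(current=(0.3, 0.0))
        sim = tr.run_simulation(self.config(), fields, (42.0, 15.0), mask)
        assert np.all(sim.base.status == tr.BEACHED)
        assert np.all(sim.base.lon > 42.8)  # anchored at the eastern coastline

    def test_release_schedule_within_window(self):
        cfg = self.config(release_duration_h=24.0)
        steps_24h = 24.0 * 60.0 / cfg.dt_minutes
        rel = tr._release_steps(cfg)
        assert rel.min() == 0
        assert rel.max() < steps_24h

    def test_particle_count_conserved(self):
        _, fields, mask = channel_setup(current=(0.1, 0.05))
        cfg = self.config(diffusivity=10.0)
        sim = tr.run_simulation(cfg, fields, (42.0, 15.0), mask)
        counts = sim.base.status_counts()
        assert sum(counts.values()) == cfg.n_particles

    def test_beached_particles_never_move_again(self):
        _, fields, mask = channel_setup(current=(0.4, 0.0))
        sim = tr.run_simulation(self.config(), fields, (42.0, 15.0), mask)
        # all beach within ~days; week-2 and week-3 snapshots must be identical
        lat2, lon2, _ = sim.week_snapshots[2]
        lat3, lon3, _ = sim.week_snapshots[3]
        assert np.array_equal(lat2, lat3) and np.array_equal(lon2, lon3)

    def test_source_on_land_rejected(self):
        _, fields, mask = channel_setup(current=(0.1, 0.0))
        with pytest.raises(ValueError, match="land"):
            tr.run_simulation(self.config(), fields, (44.0, 15.0), mask)

    def test_uncertainty_particles_travel_farther(self):
        # constant flow, no noise: perturbed forcing must increase displacement
        _, fields, _ = channel_setup(current=(0.05, 0.0))
        cfg = self.config(n_particles=100, uncertainty_scale=1.5,
                          windage=(0.0, 0.0), horizon_days=7.0,
                          release_duration_h=24.0)
        rng = np.random.default_rng(0)
        sim = tr.run_simulation(cfg, fields, (40.5, 15.0), None, rng)
        base_d = np.abs(sim.base.lon - 40.5).mean()
        unc_d = np.abs(sim.uncertainty.lon - 40.5).mean()
        assert unc_d > base_d

    def test_advection_matches_closed_form(self):
        # constant forcing: straight-line displacement to <0.1%
        _, fields, _ = channel_setup(current=(0.2, 0.1), wind=(5.0, 0.0))
        cfg = self.config(
            n_particles=4, windage=(0.02, 0.02), release_duration_h=24.0,
            horizon_days=2.0, dt_minutes=15.0,
        )
        rng = np.random.default_rng(0)
        sim = tr.run_simulation(cfg, fields, (41.0, 15.0), None, rng)
        rel = tr._release_steps(cfg)
        dt_s = cfg.dt_minutes * 60.0
        t_total = (cfg.n_steps - rel) * dt_s
        u = 0.2 + 0.02 * 5.0
        v = 0.1
        m_lat, _ = metres_per_degree(15.0)
        expected_dy = v * t_total
        actual_dy = (sim.base.lat - 15.0) * m_lat
        assert np.allclose(actual_dy, expected_dy, rtol=1e-3)
        # eastward displacement measured with the local conversion per step
        _, m_lon = metres_per_degree(sim.base.lat)
        actual_dx = (sim.base.lon - 41.0) * m_lon
        assert np.allclose(actual_dx, u * t_total, rtol=1e-3)


class TestSeasonality:
    def run_season(self, season):
        grid = GridSpec(
            lat_min=11.0, lat_max=21.0, lon_min=38.0, lon_max=46.0, cell_size=0.25,
            t_start="2020-01-01", t_end="2020-01-25", t_step_h=3.0,
        )
        fields = env.generate_environment(grid, season, seed=8)
        mask = LandMask.channel(grid, west_lon=40.0, east_lon=43.0)
        cfg = tr.TrajectoryConfig(
            n_particles=60, n_simulations=6, horizon_days=14.0,
            release_duration_h=24.0, dt_minutes=60.0,
            concentration_decimals=2, seed=21,
        )
        return tr.run_ensemble(cfg, fields, (42.8, 15.15), mask)

    def test_winter_moves_north_summer_moves_southeast(self):
        winter = self.run_season("winter")
        summer = self.run_season("summer")
        assert winter.mean_final_dlat > 0
        assert summer.mean_final_dlat < 0
        assert summer.mean_final_dlon > 0
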