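"""Euler/RK4 stepping, trajectory termination, streamlines and streamlets."""

import numpy as np
import pytest

import velostream as vs
from velostream.errors import KeyLookupError, ParameterError
from velostream.integrate import (
    TERMINATION_BELOW_THRESHOLD,
    TERMINATION_COMPLETED,
    TERMINATION_OUT_OF_DOMAIN,
)

from conftest import analytic_sink_field


@pytest.fixture
def sink():
    return analytic_sink_field(center=[5.0, 5.0, 5.0])


@pytest.fixture
def uniform_field():
    grid = vs.build_grid(np.array([[0.0, 0, 0], [10, 10, 10.0]]), 8, 0.0)
    return vs.field_from_function(grid, lambda p: np.tile([1.0, 0, 0], (len(p), 1)))


@pytest.fixture
def zero_field():
    grid = vs.build_grid(np.array([[0.0, 0, 0], [10, 10, 10.0]]), 4, 0.0)
    return vs.field_from_function(grid, lambda p: np.zeros_like(p))


class TestSteps:
    def test_zero_field_is_a_fixed_point(self, zero_field):
        p = np.array([2.0, 3.0, 4.0])
        np.testing.assert_array_equal(vs.euler_step(zero_field, p, 0.1), p)
        np.testing.assert_array_equal(vs.rk4_step(zero_field, p, 0.1), p)

    def test_uniform_field_step_arithmetic(self, uniform_field):
        p = np.array([1.0, 1.0, 1.0])
        np.testing.assert_allclose(
            vs.euler_step(uniform_field, p, 0.1), [1.1, 1.0, 1.0], atol=1e-14
        )
        # on a constant field all four RK4 slopes coincide with Euler's
        np.testing.assert_allclose(
            vs.rk4_step(uniform_field, p, 0.1), [1.1, 1.0, 1.0], atol=1e-14
        )

    def test_euler_step_on_linear_decay(self, sink):
        # v(x) = -(x - c): one Euler step from c + (1,0,0)*d contracts by (1 - h)
        start = np.array([6.0, 5.0, 5.0])
        got = vs.euler_step(sink, start, 0.1)
        np.testing.assert_allclose(got, [5.9, 5.0, 5.0], atol=1e-12)

    def test_rk4_step_matches_degree4_taylor_of_exponential(self, sink):
        h = 0.1
        start = np.array([6.0, 5.0, 5.0])
        got = vs.rk4_step(sink, start, h)
        taylor = 1 - h + h**2 / 2 - h**3 / 6 + h**4 / 24
        np.testing.assert_allclose(got[0] - 5.0, taylor, atol=1e-12)


class TestIntegrate:
    def test_zero_field_stops_below_threshold(self, zero_field):
        cfg = vs.IntegrationConfig(step_size=0.1, n_steps=10, diff_threshold=1e-6)
        traj = vs.integrate(zero_field, [2.0, 2.0, 2.0], cfg)
        assert traj.n_points == 1
        assert traj.termination == TERMINATION_BELOW_THRESHOLD

    def test_uniform_field_gives_collinear_completed_line(self, uniform_field):
        cfg = vs.IntegrationConfig(method="euler", step_size=0.1, n_steps=10,
                                   diff_threshold=0.0)
        traj = vs.integrate(uniform_field, [1.0, 5.0, 5.0], cfg)
        assert traj.n_points == 11
        assert traj.termination == TERMINATION_COMPLETED
        expect = np.array([[1.0 + 0.1 * i, 5.0, 5.0] for i in range(11)])
        np.testing.assert_allclose(traj.points, expect, atol=1e-12)

    def test_rk4_converges_to_closed_form_sink_solution(self, sink):
        cfg = vs.IntegrationConfig(method="rk4", step_size=0.05, n_steps=100,
                                   diff_threshold=0.0)
        seed = np.array([1.0, 2.0, 3.0])
        c = np.array([5.0, 5.0, 5.0])
        traj = vs.integrate(sink, seed, cfg)
        exact = c + (seed - c) * np.exp(-5.0)
        assert np.linalg.norm(traj.endpoint - exact) < 1e-6

    def test_seed_outside_hull_yields_single_point(self, sink):
        traj = vs.integrate(sink, [99.0, 0.0, 0.0], vs.IntegrationConfig())
        assert traj.n_points == 1
        assert traj.termination == TERMINATION_OUT_OF_DOMAIN

    def test_out_of_domain_keeps_last_inside_point(self, uniform_field):
        cfg = vs.IntegrationConfig(method="euler", step_size=1.0, n_steps=100,
                                   diff_threshold=0.0)
        traj = vs.integrate(uniform_field, [9.5, 5.0, 5.0], cfg)
        assert traj.termination == TERMINATION_OUT_OF_DOMAIN
        assert uniform_field.grid.contains(traj.points).all()

    def test_euler_and_rk4_identical_on_uniform_field(self, uniform_field):
        for seed in ([1.0, 2, 3], [5.0, 5, 5], [2.0, 8, 4]):
            a = vs.integrate(uniform_field, seed, vs.IntegrationConfig(
                method="euler", step_size=0.2, n_steps=20, diff_threshold=0.0))
            b = vs.integrate(uniform_field, seed, vs.IntegrationConfig(
                method="rk4", step_size=0.2, n_steps=20, diff_threshold=0.0))
            np.testing.assert_allclose(a.points, b.points, atol=1e-12)

    def test_no_consecutive_duplicate_points(self, zero_field):
        cfg = vs.IntegrationConfig(step_size=0.1, n_steps=50, diff_threshold=0.0)
        traj = vs.integrate(zero_field, [3.0, 3.0, 3.0], cfg)
        diffs = np.linalg.norm(np.diff(traj.points, axis=0), axis=1)
        assert np.all(diffs > 0)

    def test_domain_safety_on_random_fields(self):
        rng = np.random.default_rng(99)
        grid = vs.build_grid(np.array([[0.0, 0, 0], [1, 1, 1.0]]), 5, 0.0)
        voxel = grid.spacing
        for _ in range(10):
            vecs = rng.normal(scale=2.0, size=grid.shape + (3,))
            field = vs.GridVectorField(grid, vecs, np.ones(grid.shape, dtype=int))
            seed = rng.uniform(0, 1, 3)
            traj = vs.integrate(field, seed, vs.IntegrationConfig(
                method="rk4", step_size=0.3, n_steps=30, diff_threshold=0.0))
            lo = grid.origin - voxel
            hi = grid.upper + voxel
            assert np.all(traj.points >= lo) and np.all(traj.points <= hi)


class TestConvergenceOrder:
    def _endpoint_error(self, method, h, n_steps):
        field = analytic_sink_field(center=[5.0, 5.0, 5.0], resolution=6)
        seed = np.array([2.0, 3.0, 4.0])
        c = np.array([5.0, 5.0, 5.0])
        cfg = vs.IntegrationConfig(method=method, step_size=h, n_steps=n_steps,
                                   diff_threshold=0.0)
        traj = vs.integrate(field, seed, cfg)
        exact = c + (seed - c) * np.exp(-h * n_steps)
        return np.linalg.norm(traj.endpoint - exact)

    def test_euler_is_first_order(self):
        e1 = self._endpoint_error("euler", 0.1, 10)
        e2 = self._endpoint_error("euler", 0.05, 20)
        assert 1.8 <= e1 / e2 <= 2.2

    def test_rk4_is_fourth_order(self):
        e1 = self._endpoint_error("rk4", 0.1, 10)
        e2 = self._endpoint_error("rk4", 0.05, 20)
        assert 12 <= e1 / e2 <= 20


class TestSeedFromCell:
    def test_known_id_returns_coordinate_row(self, sink_dataset):
        np.testing.assert_array_equal(
            vs.seed_from_cell(sink_dataset, "cell_7"), sink_dataset.coords[7]
        )

    def test_unknown_id_raises_lookup_error(self, sink_dataset):
        with pytest.raises(KeyLookupError, match="nope"):
            vs.seed_from_cell(sink_dataset, "nope")

    def test_first_csv_row_matches_file(self, sink_dataset, tmp_path):
        import pandas as pd

        vs.write_table(sink_dataset, tmp_path / "d.csv")
        first = pd.read_csv(tmp_path / "d.csv").iloc[0]
        got = vs.seed_from_cell(sink_dataset, str(first["cell_id"]))
        np.testing.assert_allclose(got, [first["x"], first["y"], first["z"]])


class TestStreamlines:
    def test_density_one_gives_one_line_per_occupied_node(self, uniform_field):
        cfg = vs.IntegrationConfig(method="euler", step_size=0.1, n_steps=5,
                                   diff_threshold=0.0)
        lines = vs.generate_streamlines(uniform_field, cfg, density=1.0, seed=0)
        # every node is occupied; lines starting at the +x face leave immediately
        # and are dropped (< 2 points)
        nodes = uniform_field.grid.node_positions()
        expected = int((nodes[:, 0] < uniform_field.grid.upper[0]).sum())
        assert len(lines) == expected

    def test_fixed_seed_is_deterministic(self, uniform_field):
        cfg = vs.IntegrationConfig(method="euler", step_size=0.1, n_steps=5,
                                   diff_threshold=0.0)
        a = vs.generate_streamlines(uniform_field, cfg, density=0.5, seed=42)
        b = vs.generate_streamlines(uniform_field, cfg, density=0.5, seed=42)
        assert a.to_dataframe().equals(b.to_dataframe())

    def test_density_takes_floor_of_candidate_fraction(self, uniform_field):
        cfg = vs.IntegrationConfig(method="euler", step_size=0.01, n_steps=2,
                                   diff_threshold=0.0)
        n_nodes = uniform_field.grid.n_nodes
        lines = vs.generate_streamlines(uniform_field, cfg, density=0.5, seed=1)
        # seeds drawn = floor(0.5 * n_nodes); a few at the +x face drop out
        assert len(lines) <= n_nodes // 2
        seeds = {tuple(np.round(t.seed, 9)) for t in lines.trajectories}
        assert len(seeds) == len(lines)  # sampling without replacement

    def test_invalid_density_rejected(self, uniform_field):
        with pytest.raises(ParameterError):
            vs.generate_streamlines(uniform_field, vs.IntegrationConfig(), density=0.0)


class TestStreamlets:
    @pytest.fixture
    def lines(self, uniform_field):
        cfg = vs.IntegrationConfig(method="euler", step_size=0.05, n_steps=10,
                                   diff_threshold=0.0)
        return vs.generate_streamlines(uniform_field, cfg, density=0.3, seed=7)

    def test_truncation_is_a_prefix(self, lines):
        cut = vs.make_streamlets(lines, 3)
        for orig, short in zip(lines.trajectories, cut.trajectories):
            assert short.n_points == min(orig.n_points, 4)
            np.testing.assert_array_equal(short.points, orig.points[:4])

    def test_long_streamlet_steps_is_noop(self, lines):
        cut = vs.make_streamlets(lines, 10_000)
        for orig, short in zip(lines.trajectories, cut.trajectories):
            np.testing.assert_array_equal(short.points, orig.points)

    def test_total_point_count_after_truncation(self, lines):
        steps = 4
        cut = vs.make_streamlets(lines, steps)
        expect = sum(min(t.n_points, steps + 1) for t in lines.trajectories)
        assert sum(t.n_points for t in cut.trajectories) == expect
        assert cut.streamlet_steps == steps
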