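"""Unit tests for the clonal cell-layer simulator."""

import numpy as np
import pandas as pd
import pytest

from chondroshape.cell_layer import (
    Cell,
    ConfigurationError,
    DivisionClock,
    PolarizationField,
    SimConfig,
    attempt_division,
    cells_to_table,
    init_layer,
    is_proliferative,
    order_parameter,
    polarization_direction,
    resolve_overlaps,
    run_simulation,
    sample_division_direction,
    thickness_map,
    thickness_stats,
)


class TestInitLayer:
    def test_grid_monolayer(self):
        state = init_layer(4, 4, spacing=1.0, seed=7)
        table = cells_to_table(state)
        assert len(table) == 16
        assert table["clone_id"].nunique() == 16
        assert (table["z"] == 0.0).all()

    def test_single_cell_at_origin(self):
        state = init_layer(1, 1, seed=0)
        cell = next(iter(state.cells.values()))
        assert np.allclose(cell.position, [0.0, 0.0, 0.0])

    def test_seed_determinism(self):
        t1 = cells_to_table(init_layer(4, 4, seed=3))
        t2 = cells_to_table(init_layer(4, 4, seed=3))
        pd.testing.assert_frame_equal(t1, t2)

    @pytest.mark.parametrize("nx,ny,spacing", [(0, 4, 1.0), (4, -1, 1.0), (4, 4, 0.0)])
    def test_invalid_dimensions_rejected(self, nx, ny, spacing):
        with pytest.raises(ConfigurationError):
            init_layer(nx, ny, spacing=spacing)


class TestPolarizationDirection:
    def _cell(self, z):
        return Cell(id=0, clone_id=0, position=np.array([0.0, 0.0, z]))

    def test_two_sided_sign_rule(self):
        field = PolarizationField(mode="two_sided")
        up = polarization_direction(self._cell(0.6), field)
        down = polarization_direction(self._cell(-0.6), field)
        assert np.allclose(up, [0, 0, 1])
        assert np.allclose(down, [0, 0, -1])

    def test_none_is_isotropic(self):
        assert polarization_direction(self._cell(0.5), PolarizationField(mode="none")) is None

    def test_one_sided_always_up(self):
        field = PolarizationField(mode="one_sided")
        for z in (-3.0, 0.0, 3.0):
            assert np.allclose(polarization_direction(self._cell(z), field), [0, 0, 1])

    def test_extent_limits_proliferation(self):
        field = PolarizationField(mode="two_sided", extent_L=2.0)
        assert is_proliferative(self._cell(1.5), field)
        assert not is_proliferative(self._cell(2.5), field)


class TestSampleDivisionDirection:
    def test_uniform_sphere_mean_abs_projection(self, rng):
        # E|cos(theta)| = 1/2 on the uniform sphere
        draws = np.array([sample_division_direction(None, 0.0, rng) for _ in range(10_000)])
        assert abs(np.abs(draws[:, 2]).mean() - 0.5) < 0.02
        assert np.allclose(np.linalg.norm(draws, axis=1), 1.0)

    def test_high_concentration_limit(self, rng):
        mean = np.array([0.0, 0.0, 1.0])
        draws = np.array(
            [sample_division_direction(mean, 1e4, rng) for _ in range(500)]
        )
        assert np.mean(draws @ mean > 0.99) >= 0.99

    def test_seed_determinism(self):
        r1 = np.random.default_rng(5)
        r2 = np.random.default_rng(5)
        a = [sample_division_direction(np.array([0, 0, 1.0]), 3.0, r1) for _ in range(10)]
        b = [sample_division_direction(np.array([0, 0, 1.0]), 3.0, r2) for _ in range(10)]
        assert np.allclose(a, b)

    def test_negative_concentration_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_division_direction(np.array([0, 0, 1.0]), -1.0, rng)


class TestDivision:
    def test_forced_direction_places_daughter_one_diameter_up(self):
        field = PolarizationField(mode="one_sided", determinacy_b=1e8)
        state = init_layer(1, 1, seed=0, field=field)
        attempt_division(state, 0)
        daughter = state.cells[1]
        assert np.allclose(daughter.position, [0.0, 0.0, 1.0], atol=1e-3)

    def test_clone_label_inherited_and_count_conserved(self):
        state = init_layer(3, 3, seed=1)
        clones_before = {c.clone_id for c in state.cells.values()}
        attempt_division(state, 4)
        clones_after = {c.clone_id for c in state.cells.values()}
        assert clones_before == clones_after

    def test_divisions_remaining_decrements_by_one(self):
        state = init_layer(1, 1, seed=0)
        before = state.cells[0].divisions_remaining
        attempt_division(state, 0)
        assert state.cells[0].divisions_remaining == before - 1

    def test_unknown_cell_raises(self):
        state = init_layer(1, 1, seed=0)
        with pytest.raises(KeyError):
            attempt_division(state, 99)


class TestResolveOverlaps:
    def test_non_overlapping_is_fixed_point(self):
        state = init_layer(3, 3, spacing=2.0, seed=0)
        before = state.positions()
        resolve_overlaps(state)
        assert np.allclose(state.positions(), before, atol=1e-9)

    def test_coincident_cells_separated_along_x(self):
        state = init_layer(2, 1, spacing=10.0, seed=0)
        cells = list(state.cells.values())
        cells[1].position = cells[0].position.copy()
        resolve_overlaps(state)
        d = cells[1].position - cells[0].position
        assert np.linalg.norm(d) >= 2 * cells[0].radius * (1 - 0.011)
        assert abs(d[0]) > abs(d[1]) and abs(d[0]) > abs(d[2])

    def test_wall_projection(self):
        state = init_layer(2, 2, spacing=1.0, seed=0)
        cell = state.cells[0]
        cell.position = np.array([-5.0, 0.0, 0.0])  # outside the x wall
        resolve_overlaps(state)
        assert cell.position[0] >= -state.domain.x_extent / 2 + cell.radius - 1e-9


class TestRunSimulation:
    def test_no_divisions_leaves_initial_state(self):
        cfg = SimConfig(n_x=4, n_y=4, clock=DivisionClock(n_max=0), seed=2)
        state, _ = run_simulation(cfg)
        assert len(state.cells) == 16
        assert len(state.division_log) == 0

    def test_lineage_counting(self):
        # 16 founders, 3 synchronous rounds -> exactly 16 * 2^3 cells
        cfg = SimConfig(n_x=4, n_y=4, clock=DivisionClock(cv=0.0, n_max=3), seed=2)
        state, _ = run_simulation(cfg)
        assert len(state.cells) == 16 * 2**3
        counts = cells_to_table(state)["clone_id"].value_counts()
        assert (counts == 8).all()

    def test_seed_reproducibility(self):
        cfg = SimConfig(
            n_x=3, n_y=3,
            field=PolarizationField(mode="two_sided", determinacy_b=5.0),
            clock=DivisionClock(cv=0.5, n_max=3), seed=11,
        )
        s1, _ = run_simulation(cfg)
        s2, _ = run_simulation(cfg)
        assert len(s1.division_log) == len(s2.division_log)
        for (m1, d1, t1), (m2, d2, t2) in zip(s1.division_log, s2.division_log):
            assert np.array_equal(m1, m2) and np.array_equal(d1, d2) and t1 == t2

    def test_extent_cap_stops_polarized_growth(self):
        field = PolarizationField(mode="two_sided", determinacy_b=1e4, extent_L=2.0)
        cfg = SimConfig(n_x=2, n_y=2, field=field, clock=DivisionClock(n_max=8), seed=3)
        state, _ = run_simulation(cfg)
        # lineages stop once they pass the polarized extent
        assert len(state.cells) < 4 * 2**8
        # every executed division had its mother inside the polarized extent
        mother_z = np.array([abs(m[2]) for m, _, _ in state.division_log])
        assert mother_z.max() <= 2.0


class TestOrderParameter:
    def test_perfect_columns_and_in_plane(self):
        up = [(np.zeros(3), np.array([0, 0, 1.0]), 0.0)] * 5
        down = [(np.zeros(3), np.array([0, 0, -1.0]), 0.0)] * 5
        assert order_parameter(up + down).S == pytest.approx(1.0)
        flat = [(np.zeros(3), np.array([1.0, 0, 0]), 0.0),
                (np.zeros(3), np.array([0, 1.0, 0]), 0.0)]
        assert order_parameter(flat).S == pytest.approx(0.0)

    def test_uniform_directions_give_half(self, rng):
        from scipy.stats import uniform_direction

        d = uniform_direction.rvs(3, size=100_000, random_state=rng)
        log = [(np.zeros(3), v, 0.0) for v in d]
        report = order_parameter(log)
        assert report.S == pytest.approx(0.5, abs=0.01)
        assert report.n_vectors == 100_000

    def test_empty_log_rejected(self):
        with pytest.raises(ValueError):
            order_parameter([])


class TestThicknessMap:
    def test_monolayer_thickness_is_one_diameter(self):
        state = init_layer(4, 4, seed=0)
        tmap = thickness_map(state, grid_spacing=1.0)
        assert np.allclose(tmap.values[tmap.mask], 1.0)

    def test_stacked_column_thickness(self):
        state = init_layer(1, 1, seed=0)
        base = state.cells[0]
        for k in range(1, 5):
            state.cells[k] = Cell(id=k, clone_id=0,
                                  position=np.array([0.0, 0.0, float(k)]))
        tmap = thickness_map(state, grid_spacing=1.0)
        assert tmap.values[tmap.mask].max() == pytest.approx(5.0)

    def test_bump_is_map_maximum(self):
        state = init_layer(3, 3, spacing=1.0, seed=0)
        nid = 100
        for cid, cell in list(state.cells.items()):
            n_extra = 7 if cid == 4 else 1  # centre cell gets an 8-cell column
            for k in range(1, n_extra + 1):
                state.cells[nid] = Cell(id=nid, clone_id=cid,
                                        position=cell.position + [0, 0, float(k)])
                nid += 1
        tmap = thickness_map(state, grid_spacing=1.0)
        centre = tuple(np.unravel_index(np.argmax(np.where(tmap.mask, tmap.values, -1)),
                                        tmap.values.shape))
        assert centre == (1, 1)

    def test_invalid_spacing_rejected(self):
        state = init_layer(2, 2, seed=0)
        with pytest.raises(ValueError):
            thickness_map(state, grid_spacing=0.0)


class TestThicknessStats:
    def test_uniform_map_is_perfectly_regular(self):
        state = init_layer(4, 4, seed=0)
        _, regularity = thickness_stats(thickness_map(state))
        assert regularity == pytest.approx(1.0)

    def test_hand_computed_cv(self):
        from chondroshape.cell_layer import ThicknessMap

        values = np.array([[2.0, 2.0], [2.0, 6.0]])
        tmap = ThicknessMap(grid_spacing=1.0, values=values,
                            mask=np.ones((2, 2), bool),
                            x_edges=np.arange(3.0), y_edges=np.arange(3.0))
        mean, regularity = thickness_stats(tmap)
        assert mean == pytest.approx(3.0)
        assert regularity == pytest.approx(1 - np.sqrt(3) / 3, abs=1e-9)

    def test_scale_invariance(self):
        from chondroshape.cell_layer import ThicknessMap

        values = np.array([[1.0, 2.0], [3.0, 4.0]])
        m = np.ones((2, 2), bool)
        base = ThicknessMap(1.0, values, m, np.arange(3.0), np.arange(3.0))
        scaled = ThicknessMap(1.0, 7.0 * values, m, np.arange(3.0), np.arange(3.0))
        assert thickness_stats(base)[1] == pytest.approx(thickness_stats(scaled)[1])
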