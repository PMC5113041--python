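"""Engine kinematics, division, containment, scheduling and determinism."""

import io
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wormabm as w
from wormabm.engine import (
    Eggshell,
    EngineError,
    HALVE_VOLUME_RATIO,
    SimulationConfig,
    TableTriple,
    contain,
    in_eggshell,
    interphase_step,
    sample_division_time,
    split_step,
)
from wormabm.fixtures import FixtureSpec, make_fixture
from wormabm.tables_io import DivisionScheduleEntry, InitialCellSpec


class TestSplitStep:
    def test_single_tick_displacement(self):
        new = split_step((0, 0, 0), (1, 0, 0), cell_size=2.0, div_cycle_time=90.0)
        assert new == pytest.approx((2.0 / 2 / 90, 0.0, 0.0))

    def test_full_phase_displaces_half_diameter(self):
        pos = (0.0, 0.0, 0.0)
        for _ in range(90):
            pos = split_step(pos, (1, 0, 0), cell_size=2.0, div_cycle_time=90.0)
        assert pos[0] == pytest.approx(1.0, abs=1e-12)

    def test_opposite_daughters_end_one_diameter_apart(self):
        a = b = (0.0, 0.0, 0.0)
        direction = (0.0, 0.6, 0.8)
        for _ in range(90):
            a = split_step(a, direction, 2.0, 90.0)
            b = split_step(b, tuple(-c for c in direction), 2.0, 90.0)
        assert math.dist(a, b) == pytest.approx(2.0, abs=1e-12)


class TestInterphaseStep:
    def test_linear_step(self):
        new = interphase_step((0, 0, 0), (10, 0, 0), div_time=110.0, clock=100.0)
        assert new == pytest.approx((1.0, 0.0, 0.0))

    def test_iteration_arrives_exactly(self):
        pos = (0.0, 0.0, 0.0)
        for clock in range(100, 110):
            pos = interphase_step(pos, (10, 0, 0), 110.0, float(clock))
        assert pos == (10.0, 0.0, 0.0)

    def test_target_is_fixed_point(self):
        assert interphase_step((10, 0, 0), (10, 0, 0), 110.0, 100.0) == (10.0, 0.0, 0.0)

    def test_overdue_cell_is_placed_at_target(self):
        assert interphase_step((3, 4, 5), (1, 2, 3), div_time=50.0, clock=60.0) == (
            1.0,
            2.0,
            3.0,
        )


class TestEggshell:
    shell = Eggshell(center=(0, 0, 0), semi_axes=(25, 15, 15))

    def test_center_inside(self):
        assert in_eggshell((0, 0, 0), self.shell)

    def test_outside_along_major_axis(self):
        assert not in_eggshell((26, 0, 0), self.shell)

    def test_boundary_is_closed(self):
        assert in_eggshell((25, 0, 0), self.shell)

    def test_contain_keeps_inside_points(self):
        assert contain((3, 4, 5), self.shell) == (3.0, 4.0, 5.0)

    def test_contain_projects_radially(self):
        assert contain((50, 0, 0), self.shell) == pytest.approx((25.0, 0.0, 0.0))

    @given(
        st.tuples(*[st.floats(-200, 200, allow_nan=False, allow_subnormal=False)] * 3)
    )
    @settings(deadline=None, max_examples=100)
    def test_contain_is_idempotent_and_valid(self, point):
        once = contain(point, self.shell)
        assert in_eggshell(once, self.shell) or self.shell.quadratic_form(once) < 1 + 1e-9
        assert contain(once, self.shell) == pytest.approx(once, abs=1e-12)


class TestSampleDivisionTime:
    def test_unavailable_sd_is_deterministic(self):
        entry = DivisionScheduleEntry("ABala", 41.8, None, 14.8, None)
        rng = np.random.default_rng(0)
        assert sample_division_time(entry, rng) == 2508.0

    def test_zero_sd_is_mean_for_any_seed(self):
        entry = DivisionScheduleEntry("X", 41.8, 0.0, 14.8, 0.0)
        for seed in (0, 1, 99):
            rng = np.random.default_rng(seed)
            assert sample_division_time(entry, rng) == pytest.approx(2508.0)

    def test_moments_recovered_at_10k_draws(self):
        entry = DivisionScheduleEntry("X", 41.8, 0.6, 14.8, 0.6)
        rng = np.random.default_rng(42)
        draws = np.array([sample_division_time(entry, rng) for _ in range(10_000)]) / 60.0
        assert draws.mean() == pytest.approx(41.8, abs=0.02)
        assert draws.std(ddof=1) == pytest.approx(0.6, abs=0.02)

    def test_cycle_policy_offsets_from_birth(self):
        entry = DivisionScheduleEntry("X", 41.8, None, 14.8, None)
        rng = np.random.default_rng(0)
        t = sample_division_time(entry, rng, policy="cycle", born_time=120.0)
        assert t == pytest.approx(120.0 + 14.8 * 60)


class TestSetup:
    def test_founders_hatched(self, det_fixture, det_tables):
        config = SimulationConfig(end_time=600.0, rng_seed=0)
        state = w.setup(det_fixture.initial_cells, det_tables, config)
        assert state.clock == 0.0
        assert len(state.cells) == 4
        assert len({c.color_tag for c in state.cells.values()}) == 4
        for cell in state.cells.values():
            assert cell.div_direction is None  # founders skip the split phase
            assert cell.target is not None
            assert cell.next_position is not None

    def test_single_founder_degenerates_to_one_lineage(self):
        fx = make_fixture(FixtureSpec(n_founders=1, generations=1, sd_level=0.0))
        tables = TableTriple.from_entries(fx.schedule, fx.directions, fx.targets)
        state = w.setup(fx.initial_cells, tables, SimulationConfig(end_time=60.0))
        assert set(state.cells) == {fx.initial_cells[0].name}

    def test_founder_missing_from_position_table_errors(self, det_fixture, det_tables):
        tables = TableTriple(
            schedule=det_tables.schedule, directions=det_tables.directions, targets={}
        )
        with pytest.raises(EngineError, match="position table"):
            w.setup(det_fixture.initial_cells, tables, SimulationConfig(end_time=60.0))


class TestDivide:
    def test_daughters_from_tables(self, det_fixture, det_tables):
        fx = det_fixture
        config = SimulationConfig(end_time=fx.horizon_seconds, rng_seed=0)
        state = w.setup(fx.initial_cells, det_tables, config)
        parent = state.cells["ABa"]
        parent.div_time = 0.0  # force the division now
        d1, d2 = w.engine.divide(parent, det_tables, state.rng, 0.0, config)
        dentry = det_tables.directions["ABa"]
        assert (d1.name, d2.name) == (dentry.daughter1, dentry.daughter2)
        assert d1.div_direction == pytest.approx(dentry.direction)
        assert d2.div_direction == pytest.approx(tuple(-c for c in dentry.direction))
        assert d1.position == parent.position
        assert d1.div_tick == 0
        assert d1.cell_size == pytest.approx(parent.cell_size * HALVE_VOLUME_RATIO)
        assert d1.target == det_tables.targets[d1.name].target

    def test_terminal_leaf_never_divides(self):
        fx = make_fixture(FixtureSpec(n_founders=1, generations=0, sd_level=0.0))
        tables = TableTriple.from_entries(fx.schedule, fx.directions, fx.targets)
        config = SimulationConfig(end_time=fx.horizon_seconds, rng_seed=0)
        result = w.run(fx.initial_cells, tables, config)
        assert result.events == []
        assert len(result.frames[-1][1]) == 1

    def test_population_grows_by_one_per_division(self, det_run):
        counts = [len(records) for _, records in det_run.frames]
        assert counts[0] == 4
        assert counts[-1] == 16
        assert all(b - a >= 0 for a, b in zip(counts, counts[1:]))
        # total growth equals the number of division events
        assert counts[-1] - counts[0] == len(det_run.events)


class TestStepAndRun:
    def test_division_threshold_semantics(self):
        fx = make_fixture(FixtureSpec(n_founders=1, generations=1, sd_level=0.0))
        tables = TableTriple.from_entries(fx.schedule, fx.directions, fx.targets)
        config = SimulationConfig(end_time=fx.horizon_seconds, rng_seed=0)
        state = w.setup(fx.initial_cells, tables, config)
        name = fx.initial_cells[0].name
        state.cells[name].div_time = state.clock + 1.0
        w.step(state)  # clock < div_time: no division yet
        assert set(state.cells) == {name}
        w.step(state)  # clock reaches div_time: parent replaced
        assert len(state.cells) == 2
        assert name not in state.cells

    def test_snapshot_cadence(self, det_fixture, det_tables):
        config = SimulationConfig(end_time=300.0, rng_seed=0)
        result = w.run(det_fixture.initial_cells, det_tables, config)
        assert [t for t, _ in result.frames] == [0.0, 60.0, 120.0, 180.0, 240.0, 300.0]

    def test_same_seed_gives_byte_identical_output(self, noisy_fixture):
        fx = noisy_fixture
        tables = TableTriple.from_entries(fx.schedule, fx.directions, fx.targets)
        streams = []
        for _ in range(2):
            config = SimulationConfig(end_time=fx.horizon_seconds, rng_seed=7)
            result = w.run(fx.initial_cells, tables, config)
            buf = io.StringIO()
            result.write(buf)
            streams.append(buf.getvalue())
        assert streams[0] == streams[1]

    def test_seed_changes_times_not_topology(self, noisy_fixture):
        fx = noisy_fixture
        tables = TableTriple.from_entries(fx.schedule, fx.directions, fx.targets)
        trees, event_times = [], []
        for seed in (1, 2):
            config = SimulationConfig(end_time=fx.horizon_seconds, rng_seed=seed)
            result = w.run(fx.initial_cells, tables, config)
            trees.append(w.build_lineage(result.frames))
            event_times.append([e.time for e in sorted(result.events, key=lambda e: e.parent)])
        assert trees[0].same_topology(trees[1])
        assert event_times[0] != event_times[1]

    def test_cells_stay_inside_eggshell(self, det_fixture, det_tables):
        fx = det_fixture
        shell = fx.spec.eggshell
        config = SimulationConfig(end_time=fx.horizon_seconds, rng_seed=0, eggshell=shell)
        state = w.setup(fx.initial_cells, det_tables, config)
        while state.clock < config.end_time:
            w.step(state)
            for cell in state.cells.values():
                assert shell.quadratic_form(cell.position) <= 1 + 1e-9

    def test_arrival_at_target_when_deterministic(self, det_run, det_fixture):
        targets = {t.name: t.target for t in det_fixture.targets}
        for event in det_run.events:
            assert event.position == pytest.approx(targets[event.parent], abs=1e-9)

    def test_sibling_separation_after_split_phase(self):
        fx = make_fixture(FixtureSpec(n_founders=1, generations=1, sd_level=0.0, rng_seed=5))
        tables = TableTriple.from_entries(fx.schedule, fx.directions, fx.targets)
        config = SimulationConfig(
            end_time=fx.horizon_seconds,
            rng_seed=1,
            size_policy="inherit",
            eggshell=Eggshell(semi_axes=(1e6, 1e6, 1e6)),  # no boundary clipping
        )
        state = w.setup(fx.initial_cells, tables, config)
        parent_size = fx.initial_cells[0].size
        while not state.events:
            w.step(state)
        event = state.events[0]
        # daughters take their div_cycle_time split steps on the ticks
        # following the division
        while state.clock <= event.time + config.div_cycle_time:
            w.step(state)
        d1 = state.cells[event.daughter1]
        d2 = state.cells[event.daughter2]
        assert math.dist(d1.position, d2.position) == pytest.approx(
            parent_size, abs=1e-9
        )

    def test_out_resolution_must_be_multiple_of_tick(self):
        with pytest.raises(ValueError):
            SimulationConfig(end_time=100.0, out_time_resolution=90.5, tick_length=1.0)
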