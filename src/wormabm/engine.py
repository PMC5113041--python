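"""Agent-based simulation engine for early C. elegans embryogenesis.

Each live cell is an agent. Cell behavior is purely observation-driven:
the timing of a cell's division, the direction along which its daughters
separate, and the destination it migrates to are all looked up in the three
input tables (with Gaussian noise on the division time). There is no cell
death, no mechanics beyond a rigid ellipsoidal eggshell, and no gene-level
regulation — a per-agent ``extension_state`` field is reserved for future
regulatory extensions but is unused by the engine.

Movement has two regimes, selected by the per-cell tick counter
``div_tick`` (ticks elapsed since the cell's birth):

* **split phase** — for the first ``div_cycle_time`` seconds after a
  division (default 90 s) each daughter steps along its division direction
  by ``(cell_size/2)/div_cycle_time`` per tick, so that by the end of the
  phase the two sisters are fully separated by one cell diameter.
* **interphase migration** — the cell steps toward its target by
  ``(target - position)/(div_time - clock)`` per tick: a linear
  interpolation that lands the cell exactly on its target at the tick its
  division is due.

After every move the cell is clamped to the inside of the eggshell by
radial projection. A cell divides on the first tick whose clock is at or
past its (noise-perturbed) scheduled division time; the parent is replaced
by its two daughters, which inherit the parent's position and start their
own split phase.

All internal arithmetic is in seconds on a 1-second tick grid; the minute
values of the timing table are converted once at load. Cells are processed
in lexicographic name order and random draws are consumed in that same
order, so a run is fully reproducible from its seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .tables_io import (
    DivisionDirectionEntry,
    DivisionScheduleEntry,
    InitialCellSpec,
    SnapshotRecord,
    TargetPositionEntry,
    Vector3,
    read_direction_table,
    read_initial_cells,
    read_position_table,
    read_time_table,
)

logger = logging.getLogger(__name__)

SECONDS_PER_MINUTE = 60.0

__all__ = [
    "Eggshell",
    "TableTriple",
    "SimulationConfig",
    "CellAgent",
    "DivisionEvent",
    "SimulationState",
    "SimulationResult",
    "EngineError",
    "LinkageError",
    "in_eggshell",
    "contain",
    "split_step",
    "interphase_step",
    "sample_division_time",
    "default_eggshell",
    "setup",
    "divide",
    "step",
    "run",
    "link_frames",
]


class EngineError(RuntimeError):
    """Setup or stepping failed (missing table rows, name collisions, ...)."""


class LinkageError(RuntimeError):
    """A snapshot stream cannot represent the lineage (e.g. two successive
    divisions fell inside one output interval)."""


# ---------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class Eggshell:
    """Rigid ellipsoidal boundary confining all cells."""

    center: Vector3 = (0.0, 0.0, 0.0)
    semi_axes: Vector3 = (25.0, 15.0, 15.0)

    def __post_init__(self):
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError(f"semi-axes must be positive, got {self.semi_axes}")

    def quadratic_form(self, point: Sequence[float]) -> float:
        cx, cy, cz = self.center
        ax, ay, az = self.semi_axes
        return (
            ((point[0] - cx) / ax) ** 2
            + ((point[1] - cy) / ay) ** 2
            + ((point[2] - cz) / az) ** 2
        )


def in_eggshell(point: Sequence[float], shell: Eggshell) -> bool:
    """True iff ``point`` lies inside or on the (closed) ellipsoid."""
    return shell.quadratic_form(point) <= 1.0


def contain(point: Sequence[float], shell: Eggshell) -> Vector3:
    """Clamp a point to the eggshell by radial projection about its center.

    Inside points are returned unchanged; outside points are scaled onto
    the surface. Idempotent by construction.
    """
    q = shell.quadratic_form(point)
    if q <= 1.0:
        return (point[0], point[1], point[2])
    scale = 1.0 / math.sqrt(q)
    cx, cy, cz = shell.center
    return (
        cx + (point[0] - cx) * scale,
        cy + (point[1] - cy) * scale,
        cz + (point[2] - cz) * scale,
    )


def default_eggshell(
    targets: Iterable[TargetPositionEntry], margin: float = 1.1
) -> Eggshell:
    """Fit an eggshell around the target table: centered at the targets'
    centroid with per-axis semi-axes ``margin`` x the maximum absolute
    (centered) coordinate."""
    points = np.asarray([t.target for t in targets], dtype=float)
    if points.size == 0:
        return Eggshell()
    center = points.mean(axis=0)
    extent = np.abs(points - center).max(axis=0)
    semi = np.maximum(margin * extent, 1e-6)
    return Eggshell(center=tuple(center), semi_axes=tuple(semi))


# ---------------------------------------------------------------------------
# kinematics (hot path: plain-float arithmetic on 3-tuples)


def split_step(
    position: Sequence[float],
    direction: Sequence[float],
    cell_size: float,
    div_cycle_time: float,
) -> Vector3:
    """One split-phase tick: advance along the division direction so that
    ``div_cycle_time`` ticks displace the cell by half its diameter."""
    s = 0.5 * cell_size / div_cycle_time
    return (
        position[0] + direction[0] * s,
        position[1] + direction[1] * s,
        position[2] + direction[2] * s,
    )


def interphase_step(
    position: Sequence[float],
    target: Sequence[float],
    div_time: float,
    clock: float,
    tick_length: float = 1.0,
) -> Vector3:
    """One interphase tick: linear interpolation toward the target timed to
    arrive exactly when the division is due.

    When the remaining time is no more than one tick (including the
    degenerate ``div_time <= clock`` case) the cell is placed on its target
    directly, which avoids both division-by-zero and overshoot on a final
    fractional tick.
    """
    remaining = div_time - clock
    if remaining <= tick_length:
        return (target[0], target[1], target[2])
    return (
        position[0] + (target[0] - position[0]) / remaining,
        position[1] + (target[1] - position[1]) / remaining,
        position[2] + (target[2] - position[2]) / remaining,
    )


# ---------------------------------------------------------------------------
# stochastic division timing


def sample_division_time(
    entry: DivisionScheduleEntry,
    rng: np.random.Generator,
    policy: str = "absolute",
    born_time: float = 0.0,
) -> float:
    """Draw a cell's scheduled division time, in seconds.

    policy ``"absolute"`` (default)
        table's absolute division time + Normal(0, division-time SD).
    policy ``"cycle"``
        birth time + table's cycle duration + Normal(0, cycle SD).

    An unavailable SD (``None``) or an SD of zero yields the deterministic
    mean. Table values are minutes; the returned time is seconds.
    """
    if policy == "absolute":
        mean_minutes = entry.div_time
        sd = entry.div_sd
        base = 0.0
    elif policy == "cycle":
        mean_minutes = entry.cycle_time
        sd = entry.cycle_sd
        base = born_time
    else:
        raise ValueError(f"unknown sd_policy {policy!r}")
    noise = rng.normal(0.0, sd) if sd else 0.0
    return base + SECONDS_PER_MINUTE * (mean_minutes + noise)


# ---------------------------------------------------------------------------
# configuration and state


@dataclass(frozen=True)
class TableTriple:
    """The three input tables, indexed by cell name."""

    schedule: Mapping[str, DivisionScheduleEntry]
    directions: Mapping[str, DivisionDirectionEntry]
    targets: Mapping[str, TargetPositionEntry]

    @classmethod
    def from_entries(
        cls,
        schedule: Iterable[DivisionScheduleEntry],
        directions: Iterable[DivisionDirectionEntry],
        targets: Iterable[TargetPositionEntry],
    ) -> "TableTriple":
        return cls(
            schedule={e.name: e for e in schedule},
            directions={e.parent: e for e in directions},
            targets={e.name: e for e in targets},
        )

    @classmethod
    def from_files(cls, time_table, direction_table, position_table) -> "TableTriple":
        return cls.from_entries(
            read_time_table(time_table),
            read_direction_table(direction_table),
            read_position_table(position_table),
        )


@dataclass
class SimulationConfig:
    """Run parameters. Times are seconds; defaults mirror the observed
    embryo: a 90 s daughter-separation phase and 60 s output cadence."""

    end_time: float
    div_cycle_time: float = 90.0
    out_time_resolution: float = 60.0
    tick_length: float = 1.0
    eggshell: Eggshell | None = None  # None: fitted to the target table
    rng_seed: int = 0
    sd_policy: str = "absolute"
    size_policy: str = "halve_volume"  # or "inherit"

    def __post_init__(self):
        if self.div_cycle_time <= 0:
            raise ValueError("div_cycle_time must be > 0")
        if self.tick_length <= 0:
            raise ValueError("tick_length must be > 0")
        ratio = self.out_time_resolution / self.tick_length
        if self.out_time_resolution <= 0 or abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                "out_time_resolution must be a positive multiple of tick_length"
            )
        if self.size_policy not in ("halve_volume", "inherit"):
            raise ValueError(f"unknown size_policy {self.size_policy!r}")


#: daughter/parent diameter ratio under volume conservation
HALVE_VOLUME_RATIO = 2.0 ** (-1.0 / 3.0)


@dataclass
class CellAgent:
    """One live cell."""

    name: str
    cell_size: float
    position: Vector3
    div_time: float | None  # seconds; None = terminal, never divides
    div_direction: Vector3 | None  # unit vector; None for founders
    div_tick: int
    target: Vector3 | None
    color_tag: int = 0
    next_position: Vector3 | None = None
    extension_state: dict | None = None  # reserved for regulatory extensions


@dataclass(frozen=True)
class DivisionEvent:
    """One division: when it fired, who divided into whom, and where the
    parent sat when it did (its dividing position)."""

    time: float
    parent: str
    daughter1: str
    daughter2: str
    position: Vector3


@dataclass
class SimulationState:
    clock: float
    cells: dict[str, CellAgent]
    tables: TableTriple
    config: SimulationConfig
    eggshell: Eggshell
    rng: np.random.Generator
    events: list[DivisionEvent] = field(default_factory=list)
    next_snapshot_time: float = 0.0


# ---------------------------------------------------------------------------
# setup


def setup(
    initial: Sequence[InitialCellSpec],
    tables: TableTriple,
    config: SimulationConfig,
) -> SimulationState:
    """Hatch the founder cells and initialize the simulation clock.

    For each founder: name, diameter and starting position come from the
    initial-cell file; a distinct color tag marks its sublineage; the
    scheduled division time is drawn from the timing table; the migration
    target comes from the position table. Founders were not produced by an
    in-model division, so their split phase is disabled and they carry no
    division direction.
    """
    eggshell = config.eggshell or default_eggshell(tables.targets.values())
    rng = np.random.default_rng(config.rng_seed)
    cells: dict[str, CellAgent] = {}
    for color, spec in enumerate(initial):
        if spec.name in cells:
            raise EngineError(f"duplicate founder name {spec.name!r}")
        entry = tables.schedule.get(spec.name)
        if entry is None:
            raise EngineError(f"founder {spec.name!r} missing from the timing table")
        target_entry = tables.targets.get(spec.name)
        if target_entry is None:
            raise EngineError(f"founder {spec.name!r} missing from the position table")
        div_time = sample_division_time(entry, rng, config.sd_policy, born_time=0.0)
        cell = CellAgent(
            name=spec.name,
            cell_size=spec.size,
            position=tuple(spec.position),
            div_time=div_time,
            div_direction=None,
            div_tick=int(round(config.div_cycle_time / config.tick_length)),
            target=tuple(target_entry.target),
            color_tag=color,
        )
        cell.next_position = interphase_step(
            cell.position, cell.target, cell.div_time, 0.0, config.tick_length
        )
        cells[spec.name] = cell
    return SimulationState(
        clock=0.0,
        cells=cells,
        tables=tables,
        config=config,
        eggshell=eggshell,
        rng=rng,
    )


# ---------------------------------------------------------------------------
# division


def divide(
    cell: CellAgent,
    tables: TableTriple,
    rng: np.random.Generator,
    clock: float,
    config: SimulationConfig,
) -> tuple[CellAgent, CellAgent]:
    """Replace a due parent by its two daughters.

    Daughter names and daughter1's separation direction come from the
    direction table; daughter2 moves opposite. Both daughters inherit the
    parent's position and color tag, start their split phase (``div_tick``
    = 0), draw a fresh noisy division time from the timing table, and fetch
    their migration target from the position table. A daughter absent from
    the direction table is terminal and never divides; a terminal daughter
    may also lack timing/target rows, in which case it simply holds its
    position after separating.
    """
    dentry = tables.directions.get(cell.name)
    if dentry is None:
        raise EngineError(f"cell {cell.name!r} has no direction-table row")
    direction = dentry.direction
    # draw division times in sorted-name order so the random stream does not
    # depend on the daughters' column order in the table
    div_times: dict[str, float | None] = {}
    for name in sorted((dentry.daughter1, dentry.daughter2)):
        entry = tables.schedule.get(name)
        terminal = name not in tables.directions
        if entry is None:
            if not terminal:
                raise EngineError(
                    f"daughter {name!r} of {cell.name!r} divides later but has no timing row"
                )
            div_times[name] = None
        else:
            div_times[name] = sample_division_time(
                entry, rng, config.sd_policy, born_time=clock
            )
    if config.size_policy == "halve_volume":
        size = cell.cell_size * HALVE_VOLUME_RATIO
    else:
        size = cell.cell_size
    daughters = []
    for name, sign in ((dentry.daughter1, 1.0), (dentry.daughter2, -1.0)):
        target_entry = tables.targets.get(name)
        daughters.append(
            CellAgent(
                name=name,
                cell_size=size,
                position=cell.position,
                div_time=div_times[name],
                div_direction=(
                    sign * direction[0],
                    sign * direction[1],
                    sign * direction[2],
                ),
                div_tick=0,
                target=tuple(target_entry.target) if target_entry else cell.position,
                color_tag=cell.color_tag,
            )
        )
    logger.info(
        "t=%g s: %s divided into %s, %s",
        clock,
        cell.name,
        dentry.daughter1,
        dentry.daughter2,
    )
    return daughters[0], daughters[1]


# ---------------------------------------------------------------------------
# main loop


def step(state: SimulationState) -> SimulationState:
    """Advance the simulation by one tick (in place; also returned).

    Cells are visited in lexicographic name order. For each: the division
    check comes first (a due, non-terminal cell is replaced by its
    daughters, which start moving on the next tick); otherwise the cell
    takes a split-phase or interphase step and is clamped to the eggshell.
    """
    cfg = state.config
    shell = state.eggshell
    clock = state.clock
    cells = state.cells
    split_ticks = cfg.div_cycle_time / cfg.tick_length
    for name in sorted(cells):
        cell = cells.get(name)
        if cell is None:  # parent replaced earlier this tick
            continue
        if cell.div_time is not None and clock >= cell.div_time:
            if cell.name in state.tables.directions:
                d1, d2 = divide(cell, state.tables, state.rng, clock, cfg)
                del cells[cell.name]
                for daughter in (d1, d2):
                    if daughter.name in cells:
                        raise EngineError(
                            f"daughter name {daughter.name!r} already alive at t={clock}"
                        )
                    cells[daughter.name] = daughter
                state.events.append(
                    DivisionEvent(
                        time=clock,
                        parent=name,
                        daughter1=d1.name,
                        daughter2=d2.name,
                        position=cell.position,
                    )
                )
                continue
            # terminal cell past its tabulated time: holds its target
        if cell.div_tick < split_ticks and cell.div_direction is not None:
            new_pos = split_step(
                cell.position, cell.div_direction, cell.cell_size, cfg.div_cycle_time
            )
        elif cell.target is not None and cell.div_time is not None:
            new_pos = interphase_step(
                cell.position, cell.target, cell.div_time, clock, cfg.tick_length
            )
        else:
            new_pos = cell.position
        cell.position = contain(new_pos, shell)
        cell.div_tick += 1
    state.clock = clock + cfg.tick_length
    return state


@dataclass
class SimulationResult:
    """A finished run: linked snapshot frames, the division-event log and
    the final engine state."""

    frames: list[tuple[float, list[SnapshotRecord]]]
    events: list[DivisionEvent]
    state: SimulationState
    config: SimulationConfig

    def write(self, sink) -> None:
        from .tables_io import write_snapshots

        write_snapshots(self.frames, sink)


def run(
    initial: Sequence[InitialCellSpec],
    tables: TableTriple,
    config: SimulationConfig,
) -> SimulationResult:
    """Set up and step until ``config.end_time``, emitting a snapshot at
    every multiple of the output resolution (including t = 0 and, when it
    falls on the grid, the end time). Identical inputs and seed give a
    byte-identical snapshot stream."""
    state = setup(initial, tables, config)
    raw_frames: list[tuple[float, list[tuple[str, Vector3, float]]]] = []
    eps = 1e-9
    while True:
        if state.clock >= state.next_snapshot_time - eps:
            raw_frames.append(
                (
                    state.clock,
                    [
                        (c.name, c.position, c.cell_size)
                        for c in sorted(state.cells.values(), key=lambda c: c.name)
                    ],
                )
            )
            state.next_snapshot_time += config.out_time_resolution
        if state.clock >= config.end_time - eps:
            break
        step(state)
    parent_of = {}
    for event in state.events:
        parent_of[event.daughter1] = event.parent
        parent_of[event.daughter2] = event.parent
    frames = link_frames(raw_frames, parent_of)
    return SimulationResult(frames=frames, events=list(state.events), state=state, config=config)


def run_files(
    initial_file, time_table, direction_table, position_table, config: SimulationConfig
) -> SimulationResult:
    """Convenience wrapper: :func:`run` on file paths."""
    return run(
        read_initial_cells(initial_file),
        TableTriple.from_files(time_table, direction_table, position_table),
        config,
    )


# ---------------------------------------------------------------------------
# snapshot linkage


def _ancestor_in(name: str, names: set[str], parent_of: Mapping[str, str]) -> str | None:
    while name not in names:
        parent = parent_of.get(name)
        if parent is None:
            return None
        name = parent
    return name


def link_frames(
    raw_frames: Sequence[tuple[float, Sequence[tuple[str, Vector3, float]]]],
    parent_of: Mapping[str, str],
) -> list[tuple[float, list[SnapshotRecord]]]:
    """Convert raw per-frame cell lists into linked 20-field records.

    Within each frame cells are indexed 1..n in name order. Predecessor and
    successor indices are resolved by walking each cell's ancestry back to
    the neighbouring frame. A cell whose descendants at the next frame
    number more than two (two divisions inside one output interval) cannot
    be represented and raises :class:`LinkageError`.
    """
    indexed = []
    for time, cells in raw_frames:
        ordered = sorted(cells, key=lambda c: c[0])
        indexed.append((time, ordered, {c[0]: i + 1 for i, c in enumerate(ordered)}))
    frames: list[tuple[float, list[SnapshotRecord]]] = []
    for k, (time, ordered, index_of) in enumerate(indexed):
        prev_names = set(indexed[k - 1][2]) if k > 0 else set()
        if k + 1 < len(indexed):
            next_time, next_ordered, next_index = indexed[k + 1]
            successors: dict[str, list[str]] = {}
            for cell_name, _, _ in next_ordered:
                ancestor = _ancestor_in(cell_name, set(index_of), parent_of)
                if ancestor is None:
                    raise LinkageError(
                        f"cell {cell_name!r} at t={next_time} has no ancestor at t={time}"
                    )
                successors.setdefault(ancestor, []).append(cell_name)
        else:
            successors = None
        records = []
        for name, position, diameter in ordered:
            if k == 0:
                prev = -1
            else:
                ancestor = _ancestor_in(name, prev_names, parent_of)
                prev = indexed[k - 1][2][ancestor] if ancestor else -1
            if successors is None:
                nxt1, nxt2 = -1, -1
            else:
                descendants = sorted(successors.get(name, []))
                if not descendants:
                    raise LinkageError(
                        f"cell {name!r} at t={time} vanished by t={indexed[k + 1][0]}"
                    )
                if len(descendants) > 2:
                    raise LinkageError(
                        f"cell {name!r} at t={time} has {len(descendants)} descendants "
                        f"at the next frame; output resolution too coarse"
                    )
                nxt1 = next_index[descendants[0]]
                nxt2 = next_index[descendants[1]] if len(descendants) == 2 else -1
            records.append(
                SnapshotRecord(
                    index=index_of[name],
                    prev_index=prev,
                    next_index_1=nxt1,
                    next_index_2=nxt2,
                    position=position,
                    diameter=diameter,
                    name=name,
                )
            )
        frames.append((time, records))
    return frames
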