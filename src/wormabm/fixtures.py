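"""Synthetic, mutually consistent input-table triples with known ground
truth.

Real observation-derived input tables describe the invariant C. elegans
lineage; for testing the engine end to end we generate miniature analogues:
a complete binary lineage of configurable depth rooted at a handful of
founder cells, with systematic names (founder name plus ``a``/``p``
suffixes, echoing the anterior/posterior daughter nomenclature), per-cell
division times accumulated root-to-leaf, random unit division directions,
and migration targets placed strictly inside the eggshell. The generator
returns the tables *and* the lineage tree they encode, so a test can run
the engine on the tables and check that it reproduces the tree exactly.

These fixtures emulate the mechanics of real input data — consistent
naming, timing, directions and geometry — not its biology: target
positions are random rather than stereotyped, sizes are uniform, and the
depth is far short of the ~350-cell stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import Eggshell, in_eggshell
from .lineage import LineageTree
from .tables_io import (
    DivisionDirectionEntry,
    DivisionScheduleEntry,
    InitialCellSpec,
    TargetPositionEntry,
)

__all__ = ["FixtureSpec", "Fixture", "make_fixture", "make_observational_reference",
           "write_fixture", "DEFAULT_FOUNDER_NAMES"]

#: the canonical 4-cell stage
DEFAULT_FOUNDER_NAMES = ("ABa", "ABp", "EMS", "P2")

#: fraction of the eggshell within which targets are placed, leaving room
#: for split-phase excursions without boundary clipping
TARGET_SHELL_FRACTION = 0.9


class FixtureError(ValueError):
    pass


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic lineage.

    Times are minutes (matching the on-disk timing-table units):
    ``mean_cycle`` is the average cell-cycle length, ``cycle_jitter`` the
    half-width of the uniform spread of per-cell cycle means, and
    ``sd_level`` the per-cell SD written to the timing table.
    """

    n_founders: int = 4
    generations: int = 2
    mean_cycle: float = 15.0
    cycle_jitter: float = 2.0
    sd_level: float = 0.5
    founder_size: float = 6.0
    eggshell: Eggshell = field(default_factory=Eggshell)
    min_spacing: float = 0.5
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_founders < 1:
            raise FixtureError("need at least one founder")
        if self.generations < 0:
            raise FixtureError("generations must be >= 0")
        if self.mean_cycle - self.cycle_jitter <= 2.0:
            raise FixtureError(
                "minimum cycle must exceed 2 min to leave room for the 90 s split phase"
            )
        if self.sd_level < 0:
            raise FixtureError("sd_level must be >= 0")


@dataclass
class Fixture:
    """A generated input set plus the lineage it encodes."""

    spec: FixtureSpec
    initial_cells: list[InitialCellSpec]
    schedule: list[DivisionScheduleEntry]
    directions: list[DivisionDirectionEntry]
    targets: list[TargetPositionEntry]
    truth: LineageTree

    @property
    def horizon_seconds(self) -> float:
        """A run end time (s) comfortably past the last scheduled division,
        rounded up to the minute."""
        last = max(e.div_time for e in self.schedule)
        return 60.0 * (float(np.ceil(last)) + 2.0)


def _founder_names(n: int) -> list[str]:
    names = list(DEFAULT_FOUNDER_NAMES[:n])
    names += [f"F{i}" for i in range(len(names) + 1, n + 1)]
    return names


def _sample_target(rng: np.random.Generator, shell: Eggshell, placed: list,
                   min_spacing: float, max_attempts: int = 10_000):
    cx, cy, cz = shell.center
    ax, ay, az = (a * TARGET_SHELL_FRACTION for a in shell.semi_axes)
    inner = Eggshell(center=shell.center, semi_axes=(ax, ay, az))
    for _ in range(max_attempts):
        point = (
            cx + rng.uniform(-ax, ax),
            cy + rng.uniform(-ay, ay),
            cz + rng.uniform(-az, az),
        )
        if not in_eggshell(point, inner):
            continue
        if all(
            (point[0] - q[0]) ** 2 + (point[1] - q[1]) ** 2 + (point[2] - q[2]) ** 2
            >= min_spacing**2
            for q in placed
        ):
            placed.append(point)
            return point
    raise FixtureError(
        "could not place targets: eggshell too small for the requested "
        "number of cells at the given minimum spacing"
    )


def _unit_direction(rng: np.random.Generator):
    while True:
        v = rng.normal(size=3)
        norm = float(np.linalg.norm(v))
        if norm > 1e-6:
            return tuple(v / norm)


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Generate a complete binary lineage and its three input tables.

    Every node gets a timing row (absolute division time accumulated from
    the root, SD = ``sd_level``) and a target row; every internal node gets
    a direction row with a random unit vector. The returned
    :class:`LineageTree` (times in seconds) is exactly the lineage a
    noise-free engine run on these tables must reproduce.
    """
    rng = np.random.default_rng(spec.rng_seed)
    shell = spec.eggshell
    placed: list = []
    schedule: list[DivisionScheduleEntry] = []
    directions: list[DivisionDirectionEntry] = []
    targets: list[TargetPositionEntry] = []
    initial_cells: list[InitialCellSpec] = []
    truth = LineageTree()

    def cycle_minutes() -> float:
        if spec.cycle_jitter == 0:
            return spec.mean_cycle
        return spec.mean_cycle + rng.uniform(-spec.cycle_jitter, spec.cycle_jitter)

    def build(name: str, born_min: float, depth: int) -> None:
        cycle = cycle_minutes()
        div_min = born_min + cycle
        schedule.append(
            DivisionScheduleEntry(
                name=name,
                div_time=div_min,
                div_sd=spec.sd_level,
                cycle_time=cycle,
                cycle_sd=spec.sd_level,
            )
        )
        targets.append(
            TargetPositionEntry(
                name=name,
                target=_sample_target(rng, shell, placed, spec.min_spacing),
            )
        )
        if depth < spec.generations:
            d1, d2 = name + "a", name + "p"
            directions.append(
                DivisionDirectionEntry(
                    parent=name,
                    daughter1=d1,
                    daughter2=d2,
                    direction=_unit_direction(rng),
                )
            )
            truth.add_division(name, d1, d2, time=div_min * 60.0)
            build(d1, div_min, depth + 1)
            build(d2, div_min, depth + 1)

    for founder in _founder_names(spec.n_founders):
        truth.add_root(founder, born_time=0.0)
        position = _sample_target(rng, shell, placed, spec.min_spacing)
        initial_cells.append(
            InitialCellSpec(name=founder, position=position, size=spec.founder_size)
        )
        build(founder, born_min=0.0, depth=0)

    end_min = max(e.div_time for e in schedule)
    truth.end_time = end_min * 60.0
    return Fixture(
        spec=spec,
        initial_cells=initial_cells,
        schedule=schedule,
        directions=directions,
        targets=targets,
        truth=truth,
    )


def make_observational_reference(
    truth: LineageTree,
    noise_sd: float,
    rng: np.random.Generator | int | None = 0,
    born_sd: float | None = None,
    divided_sd: float | None = None,
) -> pd.DataFrame:
    """Build a cycle-analysis reference table from a ground-truth lineage.

    Stands in for wild-type observational timing data: every internal
    cell's born/divided time (seconds) is perturbed by Normal(0,
    ``noise_sd``), and the ``born_sd``/``divided_sd`` columns are set to
    the stated values (default: ``noise_sd`` itself), so tests of the
    cycle analysis know the deviation distribution by construction.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if noise_sd < 0:
        raise FixtureError("noise_sd must be >= 0")
    rows = []
    for name in sorted(truth.nodes):
        node = truth.nodes[name]
        if node.divided_time is None:
            continue
        rows.append(
            {
                "name": name,
                "born": node.born_time + (rng.normal(0.0, noise_sd) if noise_sd else 0.0),
                "born_sd": noise_sd if born_sd is None else born_sd,
                "divided": node.divided_time
                + (rng.normal(0.0, noise_sd) if noise_sd else 0.0),
                "divided_sd": noise_sd if divided_sd is None else divided_sd,
            }
        )
    return pd.DataFrame(rows).set_index("name")


def write_fixture(fixture: Fixture, outdir) -> dict[str, str]:
    """Write the four input files plus the truth tree as newick; returns
    the file paths keyed by role."""
    from pathlib import Path

    from . import lineage, tables_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "initial": outdir / "initialCells.txt",
        "time": outdir / "timeTable.txt",
        "direction": outdir / "directionTable.txt",
        "position": outdir / "positionTable.txt",
        "truth": outdir / "truth.nwk",
    }
    tables_io.write_initial_cells(fixture.initial_cells, paths["initial"])
    tables_io.write_time_table(fixture.schedule, paths["time"])
    tables_io.write_direction_table(fixture.directions, paths["direction"])
    tables_io.write_position_table(fixture.targets, paths["position"])
    paths["truth"].write_text(lineage.to_newick(fixture.truth) + "\n")
    return {k: str(v) for k, v in paths.items()}
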