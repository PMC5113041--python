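"""Input tables and the 20-field nuclei-style snapshot format.

The simulator is driven by three plain-text tables:

``timeTable``
    one row per cell: name, absolute division time (minutes), its standard
    deviation, cell-cycle duration (minutes) and its standard deviation.
    An SD of ``-1`` on disk means "not available" and is carried in memory
    as ``None`` so it can never leak into arithmetic.
``dirTable``
    one row per dividing cell: parent name, the two daughter names, and the
    3-D direction along which daughter1 separates (daughter2 moves opposite).
    Directions are normalized to unit length at load time.
``positionTable``
    one row per cell: name and the 3-D coordinate of its migration target.

plus an initial-cell file (name, x, y, z, diameter — one founder per row).

Simulation output is written in a 20-field comma-separated nuclei-tracking
record, one line per cell per emitted time point:

    index, valid, predecessor, successor1, successor2, x, y, z, diameter,
    name, then ten reserved fields (zeros, field 15 blank)

The predecessor field holds the cell's index at the previous time point
(itself or its mother, ``-1`` for none); the two successor fields hold the
indices at the next time point (itself, or its two daughters when it divides
in between; the second is ``-1`` for a non-dividing cell).
"""

from __future__ import annotations

import io
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence, Union

Vector3 = tuple[float, float, float]

TextSource = Union[str, Path, IO[str]]

__all__ = [
    "DivisionScheduleEntry",
    "DivisionDirectionEntry",
    "TargetPositionEntry",
    "InitialCellSpec",
    "SnapshotRecord",
    "TableParseError",
    "TableValidationError",
    "UnitNormWarning",
    "read_time_table",
    "read_direction_table",
    "read_position_table",
    "read_initial_cells",
    "write_time_table",
    "write_direction_table",
    "write_position_table",
    "write_initial_cells",
    "write_snapshot",
    "write_snapshots",
    "read_snapshot",
    "lint_tables",
]


class TableParseError(ValueError):
    """A row could not be parsed (wrong arity, non-numeric field, ...)."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class TableValidationError(ValueError):
    """A row parsed but violates a table invariant (duplicate name, ...)."""


class UnitNormWarning(UserWarning):
    """A raw division direction deviated noticeably from unit length."""


# ---------------------------------------------------------------------------
# domain rows


@dataclass(frozen=True)
class DivisionScheduleEntry:
    """One row of the division-timing table (all times in minutes)."""

    name: str
    div_time: float
    div_sd: float | None
    cycle_time: float
    cycle_sd: float | None


@dataclass(frozen=True)
class DivisionDirectionEntry:
    """One row of the division-direction table.

    ``direction`` is daughter1's unit displacement direction; daughter2
    moves along the negated vector.
    """

    parent: str
    daughter1: str
    daughter2: str
    direction: Vector3


@dataclass(frozen=True)
class TargetPositionEntry:
    """One row of the target-position table (embryo coordinate units)."""

    name: str
    target: Vector3


@dataclass(frozen=True)
class InitialCellSpec:
    """One founder cell: name, starting position and diameter."""

    name: str
    position: Vector3
    size: float


@dataclass
class SnapshotRecord:
    """One line of the 20-field snapshot format (linkage indices are
    1-based within a time point; ``-1`` encodes NULL)."""

    index: int
    prev_index: int
    next_index_1: int
    next_index_2: int
    position: Vector3
    diameter: float
    name: str
    valid_flag: int = 1


# ---------------------------------------------------------------------------
# low-level helpers


def _read_text(source: TextSource) -> str:
    if isinstance(source, (str, Path)):
        return Path(source).read_text()
    return source.read()


def _open_sink(sink) -> tuple[IO[str], bool]:
    if isinstance(sink, (str, Path)):
        return open(sink, "w"), True
    return sink, False


def _iter_rows(source: TextSource) -> Iterator[tuple[int, list[str]]]:
    for lineno, line in enumerate(_read_text(source).splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        yield lineno, stripped.split()


def _to_float(token: str, what: str, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise TableParseError(f"non-numeric {what} {token!r}", lineno) from None


def _to_sd(token: str, what: str, lineno: int) -> float | None:
    value = _to_float(token, what, lineno)
    if value == -1:
        return None
    if value < 0:
        raise TableValidationError(
            f"line {lineno}: {what} must be >= 0 or -1 (unavailable), got {value}"
        )
    return value


# ---------------------------------------------------------------------------
# input-table readers


def read_time_table(source: TextSource) -> list[DivisionScheduleEntry]:
    """Read the division-timing table.

    Rows are whitespace- or tab-delimited with five fields:
    name, division time (min), its SD, cycle duration (min), its SD.
    An SD of ``-1`` is mapped to ``None`` ("unavailable").
    """
    entries: list[DivisionScheduleEntry] = []
    seen: set[str] = set()
    for lineno, fields in _iter_rows(source):
        if len(fields) != 5:
            raise TableParseError(
                f"expected 5 fields (name divTime divSD cycleTime cycleSD), got {len(fields)}",
                lineno,
            )
        name = fields[0]
        if not name:
            raise TableValidationError(f"line {lineno}: empty cell name")
        if name in seen:
            raise TableValidationError(f"line {lineno}: duplicate cell name {name!r}")
        seen.add(name)
        div_time = _to_float(fields[1], "division time", lineno)
        if div_time <= 0:
            raise TableValidationError(
                f"line {lineno}: division time must be > 0, got {div_time}"
            )
        entries.append(
            DivisionScheduleEntry(
                name=name,
                div_time=div_time,
                div_sd=_to_sd(fields[2], "division-time SD", lineno),
                cycle_time=_to_float(fields[3], "cycle time", lineno),
                cycle_sd=_to_sd(fields[4], "cycle-time SD", lineno),
            )
        )
    return entries


#: relative deviation of a raw direction norm from 1 above which a warning
#: is emitted (observational direction tables are near- but not exactly unit)
NORM_WARNING_TOL = 0.10


def read_direction_table(
    source: TextSource, norm_warning_tol: float = NORM_WARNING_TOL
) -> list[DivisionDirectionEntry]:
    """Read the division-direction table (parent, daughter1, daughter2,
    dirX, dirY, dirZ).

    Directions are renormalized to unit length; a :class:`UnitNormWarning`
    is recorded when the raw norm deviates from 1 by more than
    ``norm_warning_tol``. A zero-norm direction is an error.
    """
    entries: list[DivisionDirectionEntry] = []
    seen: set[str] = set()
    for lineno, fields in _iter_rows(source):
        if len(fields) != 6:
            raise TableParseError(
                f"expected 6 fields (parent d1 d2 dirX dirY dirZ), got {len(fields)}",
                lineno,
            )
        parent, d1, d2 = fields[0], fields[1], fields[2]
        if parent in seen:
            raise TableValidationError(f"line {lineno}: duplicate parent {parent!r}")
        seen.add(parent)
        if d1 == d2:
            raise TableValidationError(
                f"line {lineno}: daughters of {parent!r} must be distinct"
            )
        raw = tuple(_to_float(fields[3 + i], "direction component", lineno) for i in range(3))
        norm = math.sqrt(raw[0] ** 2 + raw[1] ** 2 + raw[2] ** 2)
        if norm == 0.0:
            raise TableValidationError(
                f"line {lineno}: zero-norm division direction for {parent!r}"
            )
        if abs(norm - 1.0) > norm_warning_tol:
            warnings.warn(
                f"direction for {parent!r} has raw norm {norm:.4f}; renormalizing",
                UnitNormWarning,
                stacklevel=2,
            )
        direction = (raw[0] / norm, raw[1] / norm, raw[2] / norm)
        entries.append(DivisionDirectionEntry(parent, d1, d2, direction))
    return entries


def read_position_table(source: TextSource) -> list[TargetPositionEntry]:
    """Read the target-position table (name, targetX, targetY, targetZ)."""
    entries: list[TargetPositionEntry] = []
    seen: set[str] = set()
    for lineno, fields in _iter_rows(source):
        if len(fields) != 4:
            raise TableParseError(
                f"expected 4 fields (name x y z), got {len(fields)}", lineno
            )
        name = fields[0]
        if name in seen:
            raise TableValidationError(f"line {lineno}: duplicate cell name {name!r}")
        seen.add(name)
        target = tuple(_to_float(fields[1 + i], "target coordinate", lineno) for i in range(3))
        entries.append(TargetPositionEntry(name, target))
    return entries


def read_initial_cells(source: TextSource) -> list[InitialCellSpec]:
    """Read the founder-cell file (name, x, y, z, diameter)."""
    specs: list[InitialCellSpec] = []
    seen: set[str] = set()
    for lineno, fields in _iter_rows(source):
        if len(fields) != 5:
            raise TableParseError(
                f"expected 5 fields (name x y z diameter), got {len(fields)}", lineno
            )
        name = fields[0]
        if name in seen:
            raise TableValidationError(f"line {lineno}: duplicate cell name {name!r}")
        seen.add(name)
        pos = tuple(_to_float(fields[1 + i], "coordinate", lineno) for i in range(3))
        size = _to_float(fields[4], "diameter", lineno)
        if size <= 0:
            raise TableValidationError(f"line {lineno}: diameter must be > 0")
        specs.append(InitialCellSpec(name, pos, size))
    if not specs:
        raise TableValidationError("initial-cell file contains no cells")
    return specs


# ---------------------------------------------------------------------------
# input-table writers (tab-delimited; None SDs written back as -1)


def _fmt_num(value: float) -> str:
    f = float(value)
    if f.is_integer():
        return str(int(f))
    return repr(f)


def write_time_table(entries: Iterable[DivisionScheduleEntry], sink) -> None:
    fh, close = _open_sink(sink)
    try:
        for e in entries:
            sds = [
                _fmt_num(-1 if e.div_sd is None else e.div_sd),
                _fmt_num(-1 if e.cycle_sd is None else e.cycle_sd),
            ]
            fh.write(
                "\t".join([e.name, _fmt_num(e.div_time), sds[0], _fmt_num(e.cycle_time), sds[1]])
                + "\n"
            )
    finally:
        if close:
            fh.close()


def write_direction_table(entries: Iterable[DivisionDirectionEntry], sink) -> None:
    fh, close = _open_sink(sink)
    try:
        for e in entries:
            fh.write(
                "\t".join(
                    [e.parent, e.daughter1, e.daughter2]
                    + [_fmt_num(c) for c in e.direction]
                )
                + "\n"
            )
    finally:
        if close:
            fh.close()


def write_position_table(entries: Iterable[TargetPositionEntry], sink) -> None:
    fh, close = _open_sink(sink)
    try:
        for e in entries:
            fh.write("\t".join([e.name] + [_fmt_num(c) for c in e.target]) + "\n")
    finally:
        if close:
            fh.close()


def write_initial_cells(specs: Iterable[InitialCellSpec], sink) -> None:
    fh, close = _open_sink(sink)
    try:
        for s in specs:
            fh.write(
                "\t".join([s.name] + [_fmt_num(c) for c in s.position] + [_fmt_num(s.size)])
                + "\n"
            )
    finally:
        if close:
            fh.close()


# ---------------------------------------------------------------------------
# snapshot format

_N_FIELDS = 20
_TIME_HEADER = re.compile(r"^#\s*time\s+(?P<t>[-+0-9.eE]+)\s*$")


def format_snapshot_record(record: SnapshotRecord) -> str:
    """Render one record as its 20-field comma-separated line."""
    x, y, z = record.position
    fields = [
        str(record.index),
        str(record.valid_flag),
        str(record.prev_index),
        str(record.next_index_1),
        str(record.next_index_2),
        _fmt_num(x),
        _fmt_num(y),
        _fmt_num(z),
        _fmt_num(record.diameter),
        record.name,
    ]
    # ten reserved trailing fields: zeros, except field 15 which is blank
    fields += ["0", "0", "0", "0", "", "0", "0", "0", "0", "0"]
    return ", ".join(fields)


def parse_snapshot_line(line: str, lineno: int | None = None) -> SnapshotRecord:
    fields = [f.strip() for f in line.split(",")]
    if len(fields) != _N_FIELDS:
        raise TableParseError(
            f"expected {_N_FIELDS} comma-separated fields, got {len(fields)}", lineno
        )
    try:
        index = int(fields[0])
        valid = int(fields[1])
        prev_index = int(fields[2])
        next1 = int(fields[3])
        next2 = int(fields[4])
        position = (float(fields[5]), float(fields[6]), float(fields[7]))
        diameter = float(fields[8])
    except ValueError as exc:
        raise TableParseError(str(exc), lineno) from None
    if index < 1:
        raise TableValidationError(f"line {lineno}: record index must be >= 1")
    return SnapshotRecord(
        index=index,
        prev_index=prev_index,
        next_index_1=next1,
        next_index_2=next2,
        position=position,
        diameter=diameter,
        name=fields[9],
        valid_flag=valid,
    )


def write_snapshot(
    records: Sequence[SnapshotRecord], sink, time: float | None = None
) -> None:
    """Write one time point. When ``time`` is given, a ``# time <t>`` header
    line precedes the records (the concatenated-stream dialect)."""
    fh, close = _open_sink(sink)
    try:
        if time is not None:
            fh.write(f"# time {_fmt_num(time)}\n")
        for record in records:
            fh.write(format_snapshot_record(record) + "\n")
    finally:
        if close:
            fh.close()


def write_snapshots(
    frames: Sequence[tuple[float, Sequence[SnapshotRecord]]], sink
) -> None:
    """Write a concatenated snapshot stream: a ``# time`` header per frame."""
    fh, close = _open_sink(sink)
    try:
        for time, records in frames:
            write_snapshot(records, fh, time=time)
    finally:
        if close:
            fh.close()


def read_snapshot(source: TextSource) -> list[tuple[float, list[SnapshotRecord]]]:
    """Read a snapshot stream back into ``[(time, records), ...]``.

    Headerless input (a single-frame file) is returned as one frame at
    time 0. Frames are returned in increasing time order.
    """
    frames: list[tuple[float, list[SnapshotRecord]]] = []
    current: list[SnapshotRecord] | None = None
    current_time = 0.0
    for lineno, line in enumerate(_read_text(source).splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        header = _TIME_HEADER.match(stripped)
        if header:
            if current is not None:
                frames.append((current_time, current))
            current_time = float(header.group("t"))
            current = []
            continue
        if stripped.startswith("#"):
            continue
        if current is None:
            current = []
        current.append(parse_snapshot_line(stripped, lineno))
    if current is not None:
        frames.append((current_time, current))
    frames.sort(key=lambda frame: frame[0])
    return frames


# ---------------------------------------------------------------------------
# cross-table consistency


def lint_tables(
    schedule: Iterable[DivisionScheduleEntry],
    directions: Iterable[DivisionDirectionEntry],
    targets: Iterable[TargetPositionEntry],
) -> list[str]:
    """Check that the three tables are mutually consistent.

    Every daughter named in the direction table must either appear in both
    the timing and position tables, or be a terminal leaf (a cell that
    itself never divides). Returns a list of human-readable issues; an
    empty list means the triple is consistent.
    """
    schedule_names = {e.name for e in schedule}
    target_names = {e.name for e in targets}
    direction_entries = list(directions)
    parents = {e.parent for e in direction_entries}
    issues: list[str] = []
    for entry in direction_entries:
        for daughter in (entry.daughter1, entry.daughter2):
            terminal = daughter not in parents
            if daughter not in schedule_names and not terminal:
                issues.append(
                    f"daughter {daughter!r} of {entry.parent!r} divides but has no timing row"
                )
            if daughter not in target_names and not terminal:
                issues.append(
                    f"daughter {daughter!r} of {entry.parent!r} divides but has no target row"
                )
    return issues
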