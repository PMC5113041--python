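"""Cell-lineage reconstruction from snapshot streams.

The mother-daughter tree is rebuilt purely from the linkage indices of the
20-field snapshot records: a cell is tracked across time points through its
predecessor/successor indices, its birth time is the first time point at
which its name appears, and its division time is the time point at which
its two successors first appear. With the default 60 s output cadence,
born/divided times are therefore quantized to the output grid even though
the engine's internal clock is finer.

The tree can hold a forest (the four founders give four roots), exports to
newick with branch lengths equal to cell-cycle durations, and renders as
the classic lineage diagram: time runs downward, each cell is a vertical
line spanning birth to division, and a horizontal bar joins the two
daughters at the division time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .tables_io import SnapshotRecord

__all__ = ["LineageNode", "LineageTree", "LineageError", "build_lineage",
           "cell_cycle", "to_newick", "render_tree"]


class LineageError(ValueError):
    """The snapshot stream or tree violates a lineage invariant."""


@dataclass
class LineageNode:
    name: str
    parent: str | None = None
    daughters: tuple[str, ...] = ()
    born_time: float = 0.0
    divided_time: float | None = None


class LineageTree:
    """Named mother-daughter forest with born/divided times per cell."""

    def __init__(self, end_time: float | None = None):
        self.nodes: dict[str, LineageNode] = {}
        self.end_time = end_time

    # -- construction -----------------------------------------------------

    def add_root(self, name: str, born_time: float = 0.0) -> LineageNode:
        if name in self.nodes:
            raise LineageError(f"duplicate cell name {name!r}")
        node = LineageNode(name=name, born_time=born_time)
        self.nodes[name] = node
        return node

    def add_division(
        self, parent: str, daughter1: str, daughter2: str, time: float
    ) -> None:
        pnode = self.nodes.get(parent)
        if pnode is None:
            raise LineageError(f"unknown parent {parent!r}")
        if pnode.daughters:
            raise LineageError(f"cell {parent!r} divided twice")
        if daughter1 == daughter2:
            raise LineageError(f"daughters of {parent!r} must be distinct")
        if time <= pnode.born_time:
            raise LineageError(
                f"cell {parent!r} divided at {time} <= its birth {pnode.born_time}"
            )
        for name in (daughter1, daughter2):
            if name in self.nodes:
                raise LineageError(f"duplicate cell name {name!r}")
        pnode.divided_time = time
        pnode.daughters = (daughter1, daughter2)
        for name in (daughter1, daughter2):
            self.nodes[name] = LineageNode(name=name, parent=parent, born_time=time)

    # -- queries ----------------------------------------------------------

    @property
    def roots(self) -> list[str]:
        return sorted(n.name for n in self.nodes.values() if n.parent is None)

    @property
    def leaves(self) -> list[str]:
        return sorted(n.name for n in self.nodes.values() if not n.daughters)

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, name: str) -> bool:
        return name in self.nodes

    def same_topology(self, other: "LineageTree") -> bool:
        """True iff both trees have the same names and parent relations."""
        if set(self.nodes) != set(other.nodes):
            return False
        return all(
            self.nodes[name].parent == other.nodes[name].parent for name in self.nodes
        )


def cell_cycle(tree: LineageTree, name: str) -> float:
    """Cell-cycle length (seconds): division time minus birth time.

    Only defined for internal cells; a leaf (or unknown name) raises.
    """
    node = tree.nodes.get(name)
    if node is None:
        raise LineageError(f"unknown cell {name!r}")
    if node.divided_time is None:
        raise LineageError(f"cell {name!r} never divided; cycle length undefined")
    return node.divided_time - node.born_time


# ---------------------------------------------------------------------------
# reconstruction from snapshots


def build_lineage(
    frames: Sequence[tuple[float, Sequence[SnapshotRecord]]]
) -> LineageTree:
    """Rebuild the lineage from a snapshot stream.

    Every record's successor indices are followed into the next frame: one
    successor continues the same cell, two successors mark a division whose
    time is assigned to the frame at which the daughters appear. Dangling
    or inconsistent indices raise :class:`LineageError` naming the time
    point.
    """
    if not frames:
        return LineageTree(end_time=None)
    tree = LineageTree(end_time=frames[-1][0])
    t0, first = frames[0]
    for record in first:
        tree.add_root(record.name, born_time=t0)
    for k in range(len(frames) - 1):
        time, records = frames[k]
        next_time, next_records = frames[k + 1]
        by_index = {r.index: r for r in next_records}
        for record in records:
            if record.next_index_1 == -1:
                raise LineageError(
                    f"cell {record.name!r} at t={time} has no successor before t={next_time}"
                )
            succ1 = by_index.get(record.next_index_1)
            if succ1 is None:
                raise LineageError(
                    f"dangling successor index {record.next_index_1} at t={time}"
                )
            if record.next_index_2 == -1:
                if succ1.name != record.name:
                    raise LineageError(
                        f"cell {record.name!r} at t={time} continues as "
                        f"{succ1.name!r}; name changed without a division"
                    )
                if succ1.prev_index != record.index:
                    raise LineageError(
                        f"inconsistent back-link for {record.name!r} at t={next_time}"
                    )
                continue
            succ2 = by_index.get(record.next_index_2)
            if succ2 is None:
                raise LineageError(
                    f"dangling successor index {record.next_index_2} at t={time}"
                )
            for succ in (succ1, succ2):
                if succ.prev_index != record.index:
                    raise LineageError(
                        f"inconsistent back-link for daughter {succ.name!r} at t={next_time}"
                    )
            tree.add_division(record.name, succ1.name, succ2.name, next_time)
    return tree


# ---------------------------------------------------------------------------
# export


def _branch_length(tree: LineageTree, node: LineageNode) -> float:
    if node.divided_time is not None:
        return node.divided_time - node.born_time
    if len(tree.nodes) == 1 or tree.end_time is None:
        return 0.0
    return max(tree.end_time - node.born_time, 0.0)


def _fmt_len(value: float) -> str:
    return f"{value:g}"


def to_newick(tree: LineageTree) -> str:
    """Export as newick, one statement per root (a forest), with branch
    lengths equal to cell-cycle durations in seconds. Leaves carry the
    observation span from birth to the last snapshot; a single isolated
    cell gets length 0 by convention."""

    def render(name: str) -> str:
        node = tree.nodes[name]
        length = _fmt_len(_branch_length(tree, node))
        if node.daughters:
            inner = ",".join(render(d) for d in node.daughters)
            return f"({inner}){name}:{length}"
        return f"{name}:{length}"

    return "\n".join(render(root) + ";" for root in tree.roots)


def render_tree(tree: LineageTree, sink=None, ax=None):
    """Draw the lineage diagram (time downward, one vertical line per cell,
    edge length proportional to cycle time). Layout is deterministic:
    leaves are placed left-to-right in traversal order from sorted roots.

    Returns the matplotlib Axes; saves to ``sink`` when given.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, len(tree.leaves) * 0.35), 5))
    xpos: dict[str, float] = {}
    next_leaf_x = [0.0]

    def place(name: str) -> float:
        node = tree.nodes[name]
        if not node.daughters:
            xpos[name] = next_leaf_x[0]
            next_leaf_x[0] += 1.0
        else:
            xs = [place(d) for d in node.daughters]
            xpos[name] = sum(xs) / len(xs)
        return xpos[name]

    for root in tree.roots:
        place(root)
    for name, node in tree.nodes.items():
        x = xpos[name]
        bottom = node.divided_time
        if bottom is None:
            bottom = tree.end_time if tree.end_time is not None else node.born_time
        ax.plot([x, x], [node.born_time, bottom], color="black", linewidth=1.0)
        if node.daughters:
            xs = [xpos[d] for d in node.daughters]
            ax.plot([min(xs), max(xs)], [bottom, bottom], color="black", linewidth=1.0)
    ax.invert_yaxis()
    ax.set_ylabel("time (s)")
    ax.set_xticks([])
    for spine in ("top", "right", "bottom"):
        ax.spines[spine].set_visible(False)
    if sink is not None:
        ax.figure.savefig(sink, dpi=150, bbox_inches="tight")
    return ax
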