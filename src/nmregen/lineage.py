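"""Heap-encoded lineage reconstruction.

Each founder cell carries identity 1 within its own lineage; the daughters of
cell *n* receive identities 2n and 2n+1, so generation(n) = floor(log2 n) and
the parent of n > 1 is n // 2.  A division is recorded at the parent's last
frame; daughters appear one frame later near the parent's final position.

Heap indices are scoped per lineage: (lineage_id, node_index) identifies a
cell, because a single global heap numbering would collide across founders.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .track_io import ExperimentManifest, TrackTable

__all__ = [
    "LineageStructureError",
    "LineageNode",
    "DivisionEvent",
    "LineageForest",
    "build_forest",
    "generation_of",
]

#: sanity gate: daughters must first appear within this radius of the
#: parent's last position (um); None disables the check
DEFAULT_DIVISION_RADIUS_UM = 15.0


class LineageStructureError(ValueError):
    """The track table does not encode a valid binary lineage forest."""


def generation_of(node_index: int) -> int:
    """Generation of a heap node: floor(log2 n); the founder (n=1) is 0."""
    if node_index < 1:
        raise ValueError("node_index must be >= 1")
    return int(node_index).bit_length() - 1


@dataclasses.dataclass
class LineageNode:
    """One tracked cell: its lifetime, class history and trajectory."""

    lineage_id: int
    node_index: int
    times: np.ndarray  # hpi, ascending
    x: np.ndarray
    y: np.ndarray
    classes: np.ndarray  # cell_class per frame
    is_internal: bool = False  # True iff the cell divides (has daughters)

    @property
    def birth_time(self) -> float:
        return float(self.times[0])

    @property
    def end_time(self) -> float:
        return float(self.times[-1])

    @property
    def final_class(self) -> str:
        return str(self.classes[-1])

    @property
    def generation(self) -> int:
        return generation_of(self.node_index)

    @property
    def is_founder(self) -> bool:
        return self.node_index == 1

    def class_at(self, time_hpi: float) -> str:
        if not self.alive_at(time_hpi):
            raise KeyError(f"cell not alive at {time_hpi} hpi")
        i = max(0, int(np.searchsorted(self.times, time_hpi + 1e-9)) - 1)
        return str(self.classes[i])

    def position_at(self, time_hpi: float) -> tuple[float, float]:
        if not self.alive_at(time_hpi):
            raise KeyError(f"cell not alive at {time_hpi} hpi")
        i = max(0, int(np.searchsorted(self.times, time_hpi + 1e-9)) - 1)
        return float(self.x[i]), float(self.y[i])

    def alive_at(self, time_hpi: float) -> bool:
        return self.times[0] - 1e-9 <= time_hpi <= self.times[-1] + 1e-9


@dataclasses.dataclass
class DivisionEvent:
    """A cell division: the parent's last frame, place and daughters."""

    experiment_id: str
    lineage_id: int
    parent_index: int
    time_hpi: float
    x_um: float
    y_um: float
    generation: int  # of the parent
    parent_class: str

    @property
    def daughter_indices(self) -> tuple[int, int]:
        return 2 * self.parent_index, 2 * self.parent_index + 1


class LineageForest:
    """All lineage trees of one experiment."""

    def __init__(
        self,
        experiment_id: str,
        manifest: ExperimentManifest,
        trees: dict[int, dict[int, LineageNode]],
        table: TrackTable | None = None,
    ):
        self.experiment_id = experiment_id
        self.manifest = manifest
        self.trees = trees
        self.table = table

    # -- structure ---------------------------------------------------------

    @property
    def lineage_ids(self) -> list[int]:
        return sorted(self.trees)

    def node(self, lineage_id: int, node_index: int) -> LineageNode:
        return self.trees[lineage_id][node_index]

    def nodes(self) -> list[LineageNode]:
        return [n for t in self.trees.values() for n in t.values()]

    def founder(self, lineage_id: int) -> LineageNode:
        return self.trees[lineage_id][1]

    def founder_class(self, lineage_id: int) -> str:
        return str(self.founder(lineage_id).classes[0])

    def leaves(self, lineage_id: int) -> list[LineageNode]:
        return [n for n in self.trees[lineage_id].values() if not n.is_internal]

    # -- divisions ---------------------------------------------------------

    def divisions(self, lineage_id: int | None = None) -> list[DivisionEvent]:
        lids = [lineage_id] if lineage_id is not None else self.lineage_ids
        events = []
        for lid in lids:
            for n in sorted(self.trees[lid]):
                node = self.trees[lid][n]
                if node.is_internal:
                    events.append(
                        DivisionEvent(
                            experiment_id=self.experiment_id,
                            lineage_id=lid,
                            parent_index=n,
                            time_hpi=node.end_time,
                            x_um=float(node.x[-1]),
                            y_um=float(node.y[-1]),
                            generation=node.generation,
                            parent_class=node.final_class,
                        )
                    )
        events.sort(key=lambda e: (e.time_hpi, e.lineage_id, e.parent_index))
        return events

    def first_division_time(self, lineage_id: int) -> float | None:
        """When the founder of this lineage divided (hpi), or None."""
        founder = self.founder(lineage_id)
        return founder.end_time if founder.is_internal else None

    def cycle_length(self, lineage_id: int, node_index: int) -> float | None:
        """Time from birth (or recording start, for founders) to division.

        None if the cell never divides within the recording.
        """
        node = self.node(lineage_id, node_index)
        if not node.is_internal:
            return None
        start = self.manifest.start_hpi if node.is_founder else node.birth_time
        return node.end_time - start

    # -- states ------------------------------------------------------------

    def end_time(self) -> float:
        return max(n.end_time for n in self.nodes())

    def alive_at(self, time_hpi: float) -> pd.DataFrame:
        """All cells alive at a frame, with position and class."""
        rows = []
        for lid in self.lineage_ids:
            for n, node in self.trees[lid].items():
                if node.alive_at(time_hpi):
                    x, y = node.position_at(time_hpi)
                    rows.append((lid, n, x, y, node.class_at(time_hpi)))
        return pd.DataFrame(
            rows, columns=["lineage_id", "node_index", "x_um", "y_um", "cell_class"]
        )

    # -- export ------------------------------------------------------------

    def newick(self, lineage_id: int) -> str:
        """Newick string of one lineage; branch lengths are lifetimes in h.

        Node names are ``<lineage>_<node>`` (':' is reserved in Newick).
        """
        tree = self.trees[lineage_id]

        def clause(n: int) -> str:
            node = tree[n]
            name = f"{lineage_id}_{n}"
            length = node.end_time - node.birth_time
            if node.is_internal:
                kids = ",".join(clause(c) for c in (2 * n, 2 * n + 1))
                return f"({kids}){name}:{length:g}"
            return f"{name}:{length:g}"

        return clause(1) + ";"


def build_forest(
    table: TrackTable,
    division_radius_um: float | None = DEFAULT_DIVISION_RADIUS_UM,
) -> LineageForest:
    """Reconstruct the lineage forest of one experiment from its track table.

    The result is independent of the input row order (rows are grouped and
    time-sorted), and building twice yields identical structures.
    """
    df = table.data
    exp_ids = df["experiment_id"].unique()
    if len(exp_ids) != 1:
        raise LineageStructureError(
            f"expected a single experiment per table, got {sorted(exp_ids)}"
        )
    dt = table.manifest.frame_interval_h
    trees: dict[int, dict[int, LineageNode]] = {}
    for (lid, n), grp in df.groupby(["lineage_id", "node_index"], sort=True):
        grp = grp.sort_values("time_hpi")
        trees.setdefault(int(lid), {})[int(n)] = LineageNode(
            lineage_id=int(lid),
            node_index=int(n),
            times=grp["time_hpi"].to_numpy(float),
            x=grp["x_um"].to_numpy(float),
            y=grp["y_um"].to_numpy(float),
            classes=grp["cell_class"].to_numpy(object),
        )

    for lid, tree in trees.items():
        for n, node in tree.items():
            if n > 1 and n // 2 not in tree:
                raise LineageStructureError(
                    f"orphan node {n} in lineage {lid}: parent {n // 2} missing"
                )
            d1, d2 = 2 * n, 2 * n + 1
            has1, has2 = d1 in tree, d2 in tree
            if has1 != has2:
                raise LineageStructureError(
                    f"single-daughter division at node {n} of lineage {lid}"
                )
            if has1:
                node.is_internal = True
                for d in (d1, d2):
                    child = tree[d]
                    if child.birth_time <= node.end_time - dt + 1e-9:
                        raise LineageStructureError(
                            f"daughter {d} of lineage {lid} born at "
                            f"{child.birth_time} hpi before its parent "
                            f"disappeared ({node.end_time} hpi)"
                        )
                    if division_radius_um is not None:
                        dist = float(
                            np.hypot(child.x[0] - node.x[-1], child.y[0] - node.y[-1])
                        )
                        if dist > division_radius_um:
                            raise LineageStructureError(
                                f"daughter {d} of lineage {lid} appears "
                                f"{dist:.1f} um from its parent "
                                f"(gate {division_radius_um} um)"
                            )
    return LineageForest(str(exp_ids[0]), table.manifest, trees, table)
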