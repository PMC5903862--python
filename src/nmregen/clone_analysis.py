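"""Clone typing, division categorization and cell-count timecourses.

A *clone* is a founder cell together with all of its progeny.  Clones are
typed by the set of cell classes present among their members at the last
recorded timepoint: sustentacular founders give rise to S, SM, SH and SHM
clones, mantle founders to pure M clones.  A *division category* labels a
single division by the fates of its two daughters, each assessed at the time
of the daughter's own next division, or at the end of the recording if it
never divides: SS, HH, MM (symmetric) or SM (asymmetric).  Any composition
outside the observed repertoire maps to OTHER and is flagged rather than
discarded.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from collections.abc import Iterable

import numpy as np
import pandas as pd

from .lineage import DivisionEvent, LineageForest

__all__ = [
    "CLONE_TYPES",
    "DIVISION_CATEGORIES",
    "CloneRecord",
    "DivisionCategory",
    "clone_type",
    "clone_table",
    "categorize_division",
    "categorize_divisions",
    "division_summary",
    "cell_count_timecourse",
]

CLONE_TYPES = ("S", "SM", "SH", "SHM", "M", "OTHER")
DIVISION_CATEGORIES = ("SS", "HH", "MM", "SM", "OTHER")

_CLONE_MAP_S = {
    frozenset("S"): "S",
    frozenset("SM"): "SM",
    frozenset("SH"): "SH",
    frozenset("SHM"): "SHM",
}


@dataclasses.dataclass(frozen=True)
class CloneRecord:
    """Composition of one founder's clone at the end of the recording."""

    experiment_id: str
    lineage_id: int
    founder_class: str
    member_count: int  # cells alive at the last recorded timepoint
    final_classes: tuple[str, ...]  # multiset of leaf classes, sorted
    clone_type: str
    flagged: bool = False  # True for OTHER (unobserved composition)


@dataclasses.dataclass(frozen=True)
class DivisionCategory:
    """Fate pair of one division's daughters."""

    category: str
    daughter_fates: tuple[str, str]
    flagged: bool = False


def clone_type(forest: LineageForest, lineage_id: int) -> CloneRecord:
    """Type one clone from the final classes of its leaf cells."""
    leaves = forest.leaves(lineage_id)
    founder_class = forest.founder_class(lineage_id)
    finals = sorted(n.final_class for n in leaves)
    classes = frozenset(finals)
    if founder_class == "M":
        ctype = "M" if classes == frozenset("M") else "OTHER"
    else:
        ctype = _CLONE_MAP_S.get(classes, "OTHER")
    return CloneRecord(
        experiment_id=forest.experiment_id,
        lineage_id=lineage_id,
        founder_class=founder_class,
        member_count=len(leaves),
        final_classes=tuple(finals),
        clone_type=ctype,
        flagged=ctype == "OTHER",
    )


def clone_table(forests: LineageForest | Iterable[LineageForest]) -> pd.DataFrame:
    """Clone records for every founder of one or more experiments."""
    forests = [forests] if isinstance(forests, LineageForest) else list(forests)
    rows = [
        dataclasses.asdict(clone_type(f, lid))
        for f in forests
        for lid in f.lineage_ids
    ]
    df = pd.DataFrame(rows)
    df["final_classes"] = df["final_classes"].map(lambda t: "".join(t))
    return df


def _daughter_fate(forest: LineageForest, lineage_id: int, node_index: int) -> str:
    """A daughter's class at its own next division, or at recording end."""
    node = forest.node(lineage_id, node_index)
    # the class history ends either at the cell's division or at the end of
    # the recording, so the last recorded class is the assessed fate
    return node.final_class


def categorize_division(
    event: DivisionEvent, forest: LineageForest
) -> DivisionCategory:
    """Categorize one division by its daughters' assessed fates."""
    fates = tuple(
        sorted(
            _daughter_fate(forest, event.lineage_id, d)
            for d in event.daughter_indices
        )
    )
    counts = Counter(fates)
    if counts == {"S": 2}:
        cat = "SS"
    elif counts == {"H": 2}:
        cat = "HH"
    elif counts == {"M": 2}:
        cat = "MM"
    elif counts == {"M": 1, "S": 1}:
        cat = "SM"
    else:
        cat = "OTHER"
    return DivisionCategory(cat, (fates[0], fates[1]), flagged=cat == "OTHER")


def categorize_divisions(
    forests: LineageForest | Iterable[LineageForest],
) -> pd.DataFrame:
    """All divisions of one or more experiments, with categories.

    One row per division: experiment, lineage, parent node, time, place,
    generation, parent class, founder class and category.
    """
    forests = [forests] if isinstance(forests, LineageForest) else list(forests)
    rows = []
    for f in forests:
        for ev in f.divisions():
            cat = categorize_division(ev, f)
            rows.append(
                {
                    "experiment_id": ev.experiment_id,
                    "lineage_id": ev.lineage_id,
                    "parent_index": ev.parent_index,
                    "time_hpi": ev.time_hpi,
                    "x_um": ev.x_um,
                    "y_um": ev.y_um,
                    "generation": ev.generation,
                    "parent_class": ev.parent_class,
                    "founder_class": f.founder_class(ev.lineage_id),
                    "category": cat.category,
                    "flagged": cat.flagged,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "experiment_id",
            "lineage_id",
            "parent_index",
            "time_hpi",
            "x_um",
            "y_um",
            "generation",
            "parent_class",
            "founder_class",
            "category",
            "flagged",
        ],
    )


def division_summary(
    forests: LineageForest | Iterable[LineageForest],
    by: str = "parent_class",
) -> pd.DataFrame:
    """Counts and fractions of division categories per dividing-cell class.

    ``by`` may be "parent_class" (the class of the dividing cell, the
    grouping used for the 307-division tally) or "founder_class".  Fractions
    sum to 1 within each group.
    """
    if by not in {"parent_class", "founder_class"}:
        raise ValueError(f"bad grouping {by!r}")
    divs = categorize_divisions(forests)
    if divs.empty:
        raise ValueError("no divisions to summarize")
    out = (
        divs.groupby([by, "category"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = out.groupby(by)["count"].transform("sum")
    out["fraction"] = out["count"] / totals
    return out


def cell_count_timecourse(
    forests: LineageForest | Iterable[LineageForest],
    classes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-frame cell counts and class proportions.

    One row per (experiment, frame) with a count column per class, the
    total, and per-class fractions.  ``classes`` restricts which classes get
    columns (default: every class present).
    """
    forests = [forests] if isinstance(forests, LineageForest) else list(forests)
    frames = []
    for f in forests:
        nodes = f.nodes()
        times = np.unique(np.concatenate([n.times for n in nodes]))
        births = np.array([n.birth_time for n in nodes])
        ends = np.array([n.end_time for n in nodes])
        node_classes = [n.classes for n in nodes]
        node_times = [n.times for n in nodes]
        rows = []
        for t in times:
            alive = (births <= t + 1e-9) & (ends >= t - 1e-9)
            cnt: Counter[str] = Counter()
            for i in np.flatnonzero(alive):
                j = max(0, int(np.searchsorted(node_times[i], t + 1e-9)) - 1)
                cnt[str(node_classes[i][j])] += 1
            rows.append((f.experiment_id, float(t), cnt))
        frames.append(rows)

    present = classes if classes is not None else sorted(
        {c for rows in frames for _, _, cnt in rows for c in cnt}
    )
    present = list(present)
    records = []
    for rows in frames:
        for exp, t, cnt in rows:
            total = sum(cnt.values())
            rec = {"experiment_id": exp, "time_hpi": t, "total": total}
            for c in present:
                rec[f"n_{c}"] = cnt.get(c, 0)
                rec[f"frac_{c}"] = cnt.get(c, 0) / total if total else np.nan
            records.append(rec)
    return pd.DataFrame(records).sort_values(
        ["experiment_id", "time_hpi"]
    ).reset_index(drop=True)
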