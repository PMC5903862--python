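"""Organ-centered coordinates, quadrants, laterality and division maps.

The organ frame places the origin at the centroid of the founder cells'
positions at the first recorded frame (the recording is registration-centered
upstream, so the origin stays fixed for the whole movie), with +x pointing
posterior and +y dorsal.  Quadrants are the four 90-degree sectors whose
bisectors are the compass axes, half-open at the 45-degree diagonals:
dorsal [45, 135), anterior [135, 225), ventral [225, 315), posterior
otherwise.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .lineage import DivisionEvent, LineageForest
from .track_io import TrackTable

__all__ = [
    "QUADRANTS",
    "UndefinedAngleError",
    "center_tracks",
    "polar_angle",
    "quadrant_of",
    "QuadrantDistribution",
    "division_quadrant_distribution",
    "progeny_laterality",
    "division_location_map",
]

QUADRANTS = ("anterior", "posterior", "dorsal", "ventral")
POLAR_QUADRANTS = ("dorsal", "ventral")


class UndefinedAngleError(ValueError):
    """The polar angle is undefined at the origin."""


def center_tracks(table: TrackTable) -> TrackTable:
    """Translate all coordinates into the organ frame.

    Subtracts the centroid of the first frame's cells from every (x, y) and
    flips axes so that +x is posterior and +y is dorsal, per the manifest's
    axis convention.  Idempotent: re-centering a centered table is identity.
    """
    df = table.data
    if df.empty:
        raise ValueError("cannot center an empty table")
    t0 = df["time_hpi"].min()
    first = df[np.isclose(df["time_hpi"], t0)]
    if first.empty:
        raise ValueError("empty first frame")
    out = df.copy()
    if table.manifest.x_positive == "anterior":
        out["x_um"] = -out["x_um"]
    if table.manifest.y_positive == "ventral":
        out["y_um"] = -out["y_um"]
    first = out[np.isclose(out["time_hpi"], t0)]
    out["x_um"] = out["x_um"] - first["x_um"].mean()
    out["y_um"] = out["y_um"] - first["y_um"].mean()
    manifest = dataclasses.replace(
        table.manifest, x_positive="posterior", y_positive="dorsal"
    )
    return TrackTable(out, manifest)


def polar_angle(x: float, y: float) -> float:
    """Counterclockwise angle in degrees [0, 360) from the +x axis."""
    if x == 0.0 and y == 0.0:
        raise UndefinedAngleError("polar angle is undefined at the origin")
    return float(np.degrees(np.arctan2(y, x)) % 360.0)


def quadrant_of(x: float, y: float) -> str:
    """Map a point to its compass quadrant (90-degree sectors, half-open)."""
    a = polar_angle(x, y)
    if 45.0 <= a < 135.0:
        return "dorsal"
    if 135.0 <= a < 225.0:
        return "anterior"
    if 225.0 <= a < 315.0:
        return "ventral"
    return "posterior"


@dataclasses.dataclass
class QuadrantDistribution:
    """Division counts per quadrant within a time window."""

    window: tuple[float, float]
    counts: dict[str, int]
    n: int

    @property
    def empty(self) -> bool:
        return self.n == 0

    @property
    def fractions(self) -> dict[str, float] | None:
        if self.empty:
            return None
        return {q: self.counts[q] / self.n for q in QUADRANTS}

    @property
    def polar_fraction(self) -> float | None:
        """Fraction of divisions in the dorsal + ventral sectors."""
        if self.empty:
            return None
        return sum(self.counts[q] for q in POLAR_QUADRANTS) / self.n


def division_quadrant_distribution(
    events: Sequence[DivisionEvent] | pd.DataFrame,
    window: tuple[float, float],
) -> QuadrantDistribution:
    """Quadrant distribution of divisions with time in [t0, t1)."""
    t0, t1 = window
    if not t1 > t0:
        raise ValueError(f"bad window {window}")
    if isinstance(events, pd.DataFrame):
        rows = list(events[["time_hpi", "x_um", "y_um"]].itertuples(index=False))
    else:
        rows = [(e.time_hpi, e.x_um, e.y_um) for e in events]
    counts = dict.fromkeys(QUADRANTS, 0)
    n = 0
    for t, x, y in rows:
        if t0 <= t < t1:
            counts[quadrant_of(x, y)] += 1
            n += 1
    return QuadrantDistribution(window=(t0, t1), counts=counts, n=n)


def progeny_laterality(
    forest: LineageForest | Iterable[LineageForest],
    axis: str = "DV",
    t_assess: float = 60.0,
) -> pd.DataFrame:
    """Fraction of each founder's clone remaining on the founder's side.

    ``axis`` chooses the midline: "AP" splits on x (anterior = -x,
    posterior = +x), "DV" on y (ventral = -y, dorsal = +y).  For each side,
    the result pools the members of clones whose founder started on that
    side and reports the fraction found on the same side at ``t_assess``
    hpi.  Cells lying exactly on the midline are excluded from the fraction
    but counted; founders exactly on the midline are skipped with a warning.
    """
    if axis not in {"AP", "DV"}:
        raise ValueError(f"axis must be 'AP' or 'DV', got {axis!r}")
    coord = "x_um" if axis == "AP" else "y_um"
    neg, pos = ("anterior", "posterior") if axis == "AP" else ("ventral", "dorsal")

    forests = [forest] if isinstance(forest, LineageForest) else list(forest)
    tallies = {s: {"ipsi": 0, "contra": 0, "midline": 0} for s in (neg, pos)}
    for f in forests:
        state = f.alive_at(t_assess)
        for lid in f.lineage_ids:
            fnode = f.founder(lid)
            fcoord = {"x_um": fnode.x[0], "y_um": fnode.y[0]}[coord]
            if fcoord == 0.0:
                warnings.warn(
                    f"founder {lid} of {f.experiment_id} lies exactly on the "
                    f"{axis} midline; clone excluded",
                    stacklevel=2,
                )
                continue
            side = pos if fcoord > 0 else neg
            members = state[state["lineage_id"] == lid]
            for c in members[coord]:
                if c == 0.0:
                    tallies[side]["midline"] += 1
                elif (c > 0) == (fcoord > 0):
                    tallies[side]["ipsi"] += 1
                else:
                    tallies[side]["contra"] += 1

    rows = []
    for side in (neg, pos):
        t = tallies[side]
        n = t["ipsi"] + t["contra"]
        rows.append(
            {
                "side": side,
                "n_progeny": n,
                "n_midline": t["midline"],
                "ipsilateral_fraction": t["ipsi"] / n if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def division_location_map(divisions: pd.DataFrame) -> pd.DataFrame:
    """Radial-distance summary of divisions per category.

    Expects the dataframe of :func:`nmregen.clone_analysis.categorize_divisions`
    (organ-frame coordinates); returns per category the count, median and
    quartiles of the distance to the organ center.
    """
    if "category" not in divisions.columns:
        raise ValueError("divisions must carry a 'category' column")
    df = divisions.copy()
    df["radius_um"] = np.hypot(df["x_um"], df["y_um"])
    out = (
        df.groupby("category")["radius_um"]
        .agg(
            n="size",
            median_um="median",
            q1_um=lambda s: s.quantile(0.25),
            q3_um=lambda s: s.quantile(0.75),
        )
        .reset_index()
    )
    return out
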