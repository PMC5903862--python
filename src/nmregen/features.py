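"""The 32 spatial, movement and neighborhood predictors.

Every feature describes one cell at one timepoint, computed from the organ-
frame lineage forest.  Geometry is 2-D (x, y): the neuromast is a roughly
planar cuboidal epithelium, so z is carried through the files but ignored
here.  The organ center is the registration origin (0, 0) by default; a
per-frame-centroid alternative is available through :class:`FeatureConfig`.

Conventions
-----------
* "Last division" means the cell's own birth division - the time and place
  where its parent disappeared - or the recording start (at the cell's
  initial position) for founder cells.
* Distance-to-class features exclude the subject cell.  When no cell of a
  class exists at the frame (e.g. no hair cells early in regeneration) the
  distances are set to a finite sentinel (default 100 um) and the row is
  flagged, because tree learners need finite inputs.
* Whole-organ class counts include the subject; counts within a radius
  count neighbors only (the subject is excluded).
* ``movement_direction_compared_to_center`` is the radial distance at the
  last division minus the radial distance now: positive when the cell moved
  toward the center.
* ``normalized_distance_to_center`` divides by the radial distance of the
  currently furthest cell, approximating organ size; it lies in [0, 1].
* ``movement_angle_to_last_division`` is the angle at the organ center
  between the vectors to the current and to the last-division location
  (degrees in [0, 180]); a config switch moves the vertex to the
  last-division site instead.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .clone_analysis import categorize_divisions, clone_table
from .lineage import LineageForest

__all__ = ["FEATURE_NAMES", "FeatureConfig", "extract_features", "build_feature_table"]

FEATURE_NAMES = [
    "absolute_time_hpi",
    "absolute_distance_to_center",
    "average_distance_to_h_cell",
    "average_distance_to_m_cell",
    "average_distance_to_s_cell",
    "cell_generation",
    "founder_cell_type",
    "minimum_distance_to_h_cell",
    "minimum_distance_to_m_cell",
    "minimum_distance_to_s_cell",
    "movement_angle_to_last_division",
    "movement_direction_compared_to_center",
    "movement_distance_since_last_division",
    "normalized_distance_to_center",
    "number_of_founder_cells",
    "number_of_h_cells",
    "number_of_h_cells_in_10um",
    "number_of_h_cells_in_20um",
    "number_of_h_cells_in_30um",
    "number_of_m_cells",
    "number_of_m_cells_in_10um",
    "number_of_m_cells_in_20um",
    "number_of_m_cells_in_30um",
    "number_of_s_cells",
    "number_of_s_cells_in_10um",
    "number_of_s_cells_in_20um",
    "number_of_s_cells_in_30um",
    "number_of_total_cells",
    "polar_angle",
    "time_to_last_division",
    "x_coordinate",
    "y_coordinate",
]

#: features describing the cell's radial position (used e.g. when asking
#: whether center-distance information drives a classifier)
CENTER_DISTANCE_FEATURES = (
    "absolute_distance_to_center",
    "normalized_distance_to_center",
)

META_COLUMNS = [
    "experiment_id",
    "entity_id",
    "lineage_id",
    "node_index",
    "time_hpi",
    "label",
    "missing_class_flag",
]


@dataclasses.dataclass(frozen=True)
class FeatureConfig:
    sentinel_distance_um: float = 100.0
    center: str = "fixed"  # "fixed" (organ frame origin) or "frame_centroid"
    angle_vertex: str = "center"  # or "last_division"
    radii_um: tuple[float, float, float] = (10.0, 20.0, 30.0)

    def __post_init__(self) -> None:
        if self.center not in {"fixed", "frame_centroid"}:
            raise ValueError(f"bad center mode {self.center!r}")
        if self.angle_vertex not in {"center", "last_division"}:
            raise ValueError(f"bad angle vertex {self.angle_vertex!r}")


def _last_division(
    forest: LineageForest, lineage_id: int, node_index: int
) -> tuple[float, float, float]:
    """(time, x, y) of the cell's birth division / recording start."""
    node = forest.node(lineage_id, node_index)
    if node.is_founder:
        return forest.manifest.start_hpi, float(node.x[0]), float(node.y[0])
    parent = forest.node(lineage_id, node_index // 2)
    return parent.end_time, float(parent.x[-1]), float(parent.y[-1])


def _angle_between(v1: np.ndarray, v2: np.ndarray) -> float:
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        return 0.0
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def _state_features(
    forest: LineageForest,
    state: pd.DataFrame,
    subject_pos: int,
    time_hpi: float,
    config: FeatureConfig,
) -> tuple[dict[str, float], bool]:
    """Features for one subject given the frame state; returns (row, flag)."""
    xy = state[["x_um", "y_um"]].to_numpy(float)
    classes = state["cell_class"].to_numpy(object)
    center = xy.mean(axis=0) if config.center == "frame_centroid" else np.zeros(2)
    pos = xy[subject_pos]
    lid = int(state["lineage_id"].iloc[subject_pos])
    nidx = int(state["node_index"].iloc[subject_pos])
    node = forest.node(lid, nidx)

    rel = xy - center
    radii = np.linalg.norm(rel, axis=1)
    r = radii[subject_pos]
    r_max = radii.max()

    d = cdist(pos[None, :], xy)[0]
    others = np.ones(len(state), dtype=bool)
    others[subject_pos] = False

    t_ld, x_ld, y_ld = _last_division(forest, lid, nidx)
    ld = np.array([x_ld, y_ld])
    r_ld = float(np.linalg.norm(ld - center))
    if config.angle_vertex == "center":
        angle_ld = _angle_between(pos - center, ld - center)
    else:
        angle_ld = _angle_between(pos - ld, center - ld)

    if r > 0:
        theta = float(np.degrees(np.arctan2(pos[1] - center[1], pos[0] - center[0])) % 360.0)
    else:
        theta = 0.0  # angle undefined at the center; a finite stand-in

    row: dict[str, float] = {
        "absolute_time_hpi": float(time_hpi),
        "absolute_distance_to_center": float(r),
        "cell_generation": float(node.generation),
        "founder_cell_type": 1.0 if forest.founder_class(lid) == "M" else 0.0,
        "movement_angle_to_last_division": angle_ld,
        "movement_direction_compared_to_center": r_ld - float(r),
        "movement_distance_since_last_division": float(np.linalg.norm(pos - ld)),
        "normalized_distance_to_center": float(r / r_max) if r_max > 0 else 0.0,
        "number_of_founder_cells": float(len(forest.lineage_ids)),
        "number_of_total_cells": float(len(state)),
        "polar_angle": theta,
        "time_to_last_division": float(time_hpi - t_ld),
        "x_coordinate": float(pos[0]),
        "y_coordinate": float(pos[1]),
    }

    missing_flag = False
    for cls in ("H", "M", "S"):
        mask = classes == cls
        row[f"number_of_{cls.lower()}_cells"] = float(mask.sum())
        neigh = mask & others
        for radius in config.radii_um:
            row[f"number_of_{cls.lower()}_cells_in_{radius:.0f}um"] = float(
                (d[neigh] <= radius).sum()
            )
        if neigh.any():
            row[f"average_distance_to_{cls.lower()}_cell"] = float(d[neigh].mean())
            row[f"minimum_distance_to_{cls.lower()}_cell"] = float(d[neigh].min())
        else:
            row[f"average_distance_to_{cls.lower()}_cell"] = config.sentinel_distance_um
            row[f"minimum_distance_to_{cls.lower()}_cell"] = config.sentinel_distance_um
            missing_flag = True
    return row, missing_flag


def extract_features(
    forest: LineageForest,
    lineage_id: int,
    node_index: int,
    time_hpi: float,
    config: FeatureConfig | None = None,
) -> pd.Series:
    """The 32 predictors for one cell at one timepoint.

    Returns a Series indexed by :data:`FEATURE_NAMES` plus a boolean
    ``missing_class_flag`` marking sentinel-filled class distances.
    """
    config = config or FeatureConfig()
    node = forest.node(lineage_id, node_index)
    if not node.alive_at(time_hpi):
        raise KeyError(
            f"cell (lineage {lineage_id}, node {node_index}) is not alive "
            f"at {time_hpi} hpi"
        )
    state = forest.alive_at(time_hpi)
    subject = np.flatnonzero(
        (state["lineage_id"] == lineage_id) & (state["node_index"] == node_index)
    )
    row, flag = _state_features(forest, state, int(subject[0]), time_hpi, config)
    out = pd.Series({name: row[name] for name in FEATURE_NAMES})
    out["missing_class_flag"] = flag
    return out


def _frame_rows(
    forest: LineageForest,
    requests: list[tuple[float, int, int, str, str]],
    config: FeatureConfig,
) -> list[dict]:
    """Extract features for many (time, cell) requests, one state per frame."""
    rows: list[dict] = []
    by_time: dict[float, list[tuple[int, int, str, str]]] = {}
    for t, lid, nidx, entity, label in requests:
        by_time.setdefault(round(float(t), 9), []).append((lid, nidx, entity, label))
    for t in sorted(by_time):
        state = forest.alive_at(t)
        index = {
            (int(l), int(n)): i
            for i, (l, n) in enumerate(
                zip(state["lineage_id"], state["node_index"])
            )
        }
        for lid, nidx, entity, label in by_time[t]:
            vals, flag = _state_features(
                forest, state, index[(lid, nidx)], t, config
            )
            vals.update(
                experiment_id=forest.experiment_id,
                entity_id=entity,
                lineage_id=lid,
                node_index=nidx,
                time_hpi=t,
                label=label,
                missing_class_flag=flag,
            )
            rows.append(vals)
    return rows


def build_feature_table(
    forests: LineageForest | Iterable[LineageForest],
    task_level: str,
    config: FeatureConfig | None = None,
    division_window_frames: int = 1,
) -> pd.DataFrame:
    """Labeled feature rows for clone- or division-level prediction.

    ``task_level`` selects the row policy:

    * ``"clone"`` - for every sustentacular founder, one row per frame from
      the recording start until (and including) its first division, labeled
      with the clone type.  The founder is the entity.
    * ``"division"`` - for every sustentacular-cell division, rows for the
      dividing cell over the ``division_window_frames`` frames ending at
      the division, labeled with the division category.  The division is
      the entity.

    Raises ``ValueError`` if the policy selects no rows.
    """
    if task_level not in {"clone", "division"}:
        raise ValueError(f"bad task level {task_level!r}")
    config = config or FeatureConfig()
    forests = [forests] if isinstance(forests, LineageForest) else list(forests)

    all_rows: list[dict] = []
    for f in forests:
        dt = f.manifest.frame_interval_h
        requests: list[tuple[float, int, int, str, str]] = []
        if task_level == "clone":
            clones = clone_table(f)
            for rec in clones.itertuples(index=False):
                if rec.founder_class != "S":
                    continue
                founder = f.founder(rec.lineage_id)
                t_stop = founder.end_time
                entity = f"{f.experiment_id}:{rec.lineage_id}"
                for t in founder.times:
                    if t <= t_stop + 1e-9:
                        requests.append(
                            (float(t), rec.lineage_id, 1, entity, rec.clone_type)
                        )
        else:
            divs = categorize_divisions(f)
            for rec in divs.itertuples(index=False):
                if rec.parent_class != "S":
                    continue
                entity = f"{f.experiment_id}:{rec.lineage_id}:{rec.parent_index}"
                node = f.node(rec.lineage_id, rec.parent_index)
                for k in range(division_window_frames):
                    t = rec.time_hpi - k * dt
                    if node.alive_at(t):
                        requests.append(
                            (
                                float(t),
                                rec.lineage_id,
                                rec.parent_index,
                                entity,
                                rec.category,
                            )
                        )
        all_rows.extend(_frame_rows(f, requests, config))

    if not all_rows:
        raise ValueError(f"row policy {task_level!r} selected no rows")
    df = pd.DataFrame(all_rows)
    return df[META_COLUMNS + FEATURE_NAMES]
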