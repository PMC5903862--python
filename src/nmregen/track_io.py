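"""Reading, validation and writing of neuromast track tables.

The on-disk dialect is a plain UTF-8 CSV with a fixed header and one row per
cell per frame::

    experiment_id,lineage_id,node_index,time_hpi,x_um,y_um,z_um,cell_class

``lineage_id`` labels a founder cell (unique within an experiment) and
``node_index`` is the within-lineage heap position: the founder is 1, and the
daughters of cell *n* are 2n and 2n+1.  Times are hours post injury (hpi) on
the acquisition grid declared in the experiment manifest (default: recording
starts 4.0 hpi, one frame every 0.25 h).  ``cell_class`` is one of S
(sustentacular), M (mantle), H (hair) or U (unassigned).

Hair cells are postmitotic and terminal, so the only class changes a valid
table may contain for a given cell are S->M, S->H and U->{S,M,H}.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "COLUMNS",
    "CELL_CLASSES",
    "TrackFormatError",
    "TrackValidationError",
    "ExperimentManifest",
    "TrackTable",
    "validate_tracks",
    "read_tracks",
    "write_tracks",
    "read_manifest",
    "write_manifest",
]

COLUMNS = [
    "experiment_id",
    "lineage_id",
    "node_index",
    "time_hpi",
    "x_um",
    "y_um",
    "z_um",
    "cell_class",
]

CELL_CLASSES = {"S", "M", "H", "U"}

#: class transitions a cell may undergo over time (besides staying the same)
ALLOWED_TRANSITIONS = {
    ("S", "M"),
    ("S", "H"),
    ("U", "S"),
    ("U", "M"),
    ("U", "H"),
}

_FLOAT_FMT = "%.6f"
_GRID_TOL = 1e-6


class TrackFormatError(ValueError):
    """The file does not conform to the track-table dialect."""


class TrackValidationError(ValueError):
    """The table is well-formed but violates a track invariant."""


@dataclasses.dataclass(frozen=True)
class ExperimentManifest:
    """Per-experiment acquisition metadata.

    ``x_positive`` / ``y_positive`` name the anatomical direction of the
    positive world axes; the analysis frame is +x = posterior, +y = dorsal.
    """

    experiment_id: str
    frame_interval_h: float = 0.25
    start_hpi: float = 4.0
    duration_h: float = 96.0
    founder_count: int = 1
    x_positive: str = "posterior"
    y_positive: str = "dorsal"

    def __post_init__(self) -> None:
        if self.frame_interval_h <= 0:
            raise ValueError("frame_interval_h must be positive")
        if self.duration_h <= 0:
            raise ValueError("duration_h must be positive")
        if self.founder_count < 1:
            raise ValueError("founder_count must be >= 1")
        if self.x_positive not in {"posterior", "anterior"}:
            raise ValueError(f"bad x_positive: {self.x_positive!r}")
        if self.y_positive not in {"dorsal", "ventral"}:
            raise ValueError(f"bad y_positive: {self.y_positive!r}")

    @property
    def end_hpi(self) -> float:
        return self.start_hpi + self.duration_h

    def frame_times(self) -> np.ndarray:
        """All acquisition times (hpi) of the recording."""
        n = int(math.floor(self.duration_h / self.frame_interval_h + _GRID_TOL))
        return self.start_hpi + self.frame_interval_h * np.arange(n + 1)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentManifest":
        return cls(**d)


def read_manifest(path: str | Path) -> ExperimentManifest:
    """Read a manifest from a YAML or JSON key-value file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise TrackFormatError(f"manifest {path} is not a key-value mapping")
    try:
        return ExperimentManifest.from_dict(data)
    except TypeError as exc:
        raise TrackFormatError(f"manifest {path}: {exc}") from None


def write_manifest(manifest: ExperimentManifest, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(manifest.to_dict(), indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(manifest.to_dict(), sort_keys=False))


@dataclasses.dataclass
class TrackTable:
    """A validated track table together with its manifest.

    ``data`` holds one row per (cell, frame) with the columns of
    :data:`COLUMNS`, sorted by (lineage_id, node_index, time_hpi).
    """

    data: pd.DataFrame
    manifest: ExperimentManifest

    def __len__(self) -> int:
        return len(self.data)

    @property
    def lineage_ids(self) -> list[int]:
        return sorted(self.data["lineage_id"].unique().tolist())

    @property
    def n_lineages(self) -> int:
        return self.data["lineage_id"].nunique()

    def frame_of(self, time_hpi: float) -> pd.DataFrame:
        return self.data[np.isclose(self.data["time_hpi"], time_hpi)]


def _sorted(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(
        ["lineage_id", "node_index", "time_hpi"], kind="mergesort"
    ).reset_index(drop=True)


def validate_tracks(df: pd.DataFrame, manifest: ExperimentManifest) -> pd.DataFrame:
    """Validate a raw dataframe against the track invariants.

    Returns the coerced, sorted dataframe; raises :class:`TrackFormatError`
    for dialect problems and :class:`TrackValidationError` for invariant
    violations, citing the offending column or row.
    """
    for col in COLUMNS:
        if col == "z_um" and col not in df.columns:
            continue  # z is optional; filled with 0 below
        if col not in df.columns:
            raise TrackFormatError(f"missing column {col!r}")
    df = df.copy()
    if "z_um" not in df.columns:
        df["z_um"] = 0.0
    df["z_um"] = pd.to_numeric(df["z_um"], errors="coerce").fillna(0.0)
    for col in ("time_hpi", "x_um", "y_um"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
        if df[col].isna().any():
            row = int(df.index[df[col].isna()][0])
            raise TrackFormatError(f"non-numeric value in column {col!r} at row {row}")
    for col in ("lineage_id", "node_index"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any() or (vals != vals.round()).any():
            raise TrackFormatError(f"column {col!r} must contain integers")
        df[col] = vals.astype(np.int64)
        if (df[col] < 1).any():
            row = int(df.index[df[col] < 1][0])
            raise TrackValidationError(f"{col} must be >= 1 (row {row})")
    df["experiment_id"] = df["experiment_id"].astype(str)
    df["cell_class"] = df["cell_class"].astype(str)

    bad = ~df["cell_class"].isin(CELL_CLASSES)
    if bad.any():
        row = int(df.index[bad][0])
        raise TrackValidationError(
            f"unknown cell_class {df.loc[row, 'cell_class']!r} at row {row}"
        )
    if (df["time_hpi"] < 0).any():
        raise TrackValidationError("time_hpi must be non-negative")

    df = _sorted(df[COLUMNS])

    dup = df.duplicated(["experiment_id", "lineage_id", "node_index", "time_hpi"])
    if dup.any():
        r = df[dup].iloc[0]
        raise TrackValidationError(
            "duplicate (experiment, lineage, node, time) row: "
            f"({r.experiment_id}, {r.lineage_id}, {r.node_index}, {r.time_hpi})"
        )

    # time grid alignment against the manifest
    k = (df["time_hpi"] - manifest.start_hpi) / manifest.frame_interval_h
    off = np.abs(k - np.round(k)) > _GRID_TOL
    if off.any():
        r = df[off].iloc[0]
        raise TrackValidationError(
            f"time {r.time_hpi} hpi is off the acquisition grid "
            f"(start {manifest.start_hpi}, interval {manifest.frame_interval_h})"
        )
    if (df["time_hpi"] > manifest.end_hpi + _GRID_TOL).any():
        raise TrackValidationError("time_hpi beyond the recording duration")

    # per-cell class sequences obey the allowed transition set
    for (lid, node), grp in df.groupby(["lineage_id", "node_index"], sort=False):
        classes = grp["cell_class"].to_numpy()
        for a, b in zip(classes[:-1], classes[1:]):
            if a != b and (a, b) not in ALLOWED_TRANSITIONS:
                raise TrackValidationError(
                    f"illegal class transition {a}->{b} for cell "
                    f"(lineage {lid}, node {node})"
                )
    return df


def read_tracks(path: str | Path, manifest: ExperimentManifest) -> TrackTable:
    """Read and validate a track CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, dtype={"experiment_id": str, "cell_class": str})
    except pd.errors.EmptyDataError:
        raise TrackFormatError(f"{path} is empty (no header)") from None
    return TrackTable(validate_tracks(df, manifest), manifest)


def write_tracks(table: TrackTable, path: str | Path) -> None:
    """Write a track table with deterministic column and row order."""
    df = _sorted(table.data[COLUMNS])
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
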