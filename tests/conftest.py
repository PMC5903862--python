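"""Shared fixtures: tiny hand-built tables and session-scoped cohorts."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from nmregen import synthetic_data as sd
from nmregen.lineage import build_forest
from nmregen.spatial import center_tracks
from nmregen.track_io import COLUMNS, ExperimentManifest, TrackTable, validate_tracks


def make_table(rows, manifest=None, **manifest_kwargs) -> TrackTable:
    """Build a validated TrackTable from (lineage, node, t, x, y, cls) rows."""
    manifest = manifest or ExperimentManifest(
        experiment_id="T", duration_h=96.0, **manifest_kwargs
    )
    df = pd.DataFrame(
        [
            {
                "experiment_id": manifest.experiment_id,
                "lineage_id": lid,
                "node_index": node,
                "time_hpi": t,
                "x_um": x,
                "y_um": y,
                "z_um": 0.0,
                "cell_class": cls,
            }
            for lid, node, t, x, y, cls in rows
        ],
        columns=COLUMNS,
    )
    return TrackTable(validate_tracks(df, manifest), manifest)


def cell_track(lid, node, t0, t1, cls, x=0.0, y=0.0, dt=0.25):
    """Rows for one stationary cell alive over [t0, t1]."""
    times = np.arange(t0, t1 + dt / 2, dt)
    return [(lid, node, float(t), x, y, cls) for t in times]


@pytest.fixture(scope="session")
def default_config() -> sd.SimulationConfig:
    return sd.SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def cohort(default_config):
    """The default 15-experiment synthetic cohort (study conditions)."""
    return sd.generate_cohort(default_config)


@pytest.fixture(scope="session")
def forests(cohort):
    """Centered lineage forests of the default cohort."""
    return [build_forest(center_tracks(e.table)) for e in cohort]


@pytest.fixture(scope="session")
def null_cohort(default_config):
    return sd.generate_cohort(sd.null_variant(default_config))


@pytest.fixture(scope="session")
def null_forests(null_cohort):
    return [build_forest(center_tracks(e.table)) for e in null_cohort]


@pytest.fixture(scope="session")
def division_features(forests):
    from nmregen.features import build_feature_table

    return build_feature_table(forests, "division")


@pytest.fixture(scope="session")
def clone_features(forests):
    from nmregen.features import build_feature_table

    return build_feature_table(forests, "clone")
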