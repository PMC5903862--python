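"""The 32 predictors: against a brute-force oracle and invariances."""

import numpy as np
import pandas as pd
import pytest

from nmregen.features import (
    FEATURE_NAMES,
    FeatureConfig,
    build_feature_table,
    extract_features,
)
from nmregen.lineage import build_forest

from conftest import cell_track, make_table


def brute_force_features(state, subject, center, config, forest_info):
    """Independent recomputation with naive double loops.

    ``state`` is a list of (lineage, node, x, y, cls); ``forest_info`` a dict
    with generation, founder class, founder count, last-division data and
    times for the subject.
    """
    sx, sy = None, None
    for lid, node, x, y, cls in state:
        if (lid, node) == subject:
            sx, sy = x, y
            scls = cls
    out = {}
    cx, cy = center
    r = np.sqrt((sx - cx) ** 2 + (sy - cy) ** 2)
    out["absolute_distance_to_center"] = r
    rmax = max(np.sqrt((x - cx) ** 2 + (y - cy) ** 2) for _, _, x, y, _ in state)
    out["normalized_distance_to_center"] = r / rmax if rmax > 0 else 0.0
    out["polar_angle"] = (np.degrees(np.arctan2(sy - cy, sx - cx)) % 360.0) if r > 0 else 0.0
    out["x_coordinate"], out["y_coordinate"] = sx, sy
    out["number_of_total_cells"] = len(state)
    for cls in "HMS":
        dists = []
        n_total = 0
        in_radius = {10.0: 0, 20.0: 0, 30.0: 0}
        for lid, node, x, y, c in state:
            if c != cls:
                continue
            n_total += 1
            if (lid, node) == subject:
                continue
            d = np.sqrt((x - sx) ** 2 + (y - sy) ** 2)
            dists.append(d)
            for radius in in_radius:
                if d <= radius:
                    in_radius[radius] += 1
        lc = cls.lower()
        out[f"number_of_{lc}_cells"] = n_total
        for radius, n in in_radius.items():
            out[f"number_of_{lc}_cells_in_{radius:.0f}um"] = n
        out[f"average_distance_to_{lc}_cell"] = (
            float(np.mean(dists)) if dists else config.sentinel_distance_um
        )
        out[f"minimum_distance_to_{lc}_cell"] = (
            float(np.min(dists)) if dists else config.sentinel_distance_um
        )
    t_ld, x_ld, y_ld = forest_info["last_division"]
    out["time_to_last_division"] = forest_info["time"] - t_ld
    out["movement_distance_since_last_division"] = np.sqrt(
        (sx - x_ld) ** 2 + (sy - y_ld) ** 2
    )
    out["movement_direction_compared_to_center"] = np.sqrt(
        (x_ld - cx) ** 2 + (y_ld - cy) ** 2
    ) - r
    v1 = np.array([sx - cx, sy - cy])
    v2 = np.array([x_ld - cx, y_ld - cy])
    if np.linalg.norm(v1) == 0 or np.linalg.norm(v2) == 0:
        out["movement_angle_to_last_division"] = 0.0
    else:
        c = np.clip(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1, 1)
        out["movement_angle_to_last_division"] = float(np.degrees(np.arccos(c)))
    out["absolute_time_hpi"] = forest_info["time"]
    out["cell_generation"] = forest_info["generation"]
    out["founder_cell_type"] = forest_info["founder_type"]
    out["number_of_founder_cells"] = forest_info["n_founders"]
    return out


def test_feature_name_list_is_complete():
    assert len(FEATURE_NAMES) == 32
    assert len(set(FEATURE_NAMES)) == 32


def test_simple_geometry_by_hand():
    rows = (
        cell_track(1, 1, 4.0, 10.0, "S", x=0.0, y=10.0)
        + cell_track(2, 1, 4.0, 10.0, "M", x=0.0, y=-10.0)
    )
    f = build_forest(make_table(rows))
    v = extract_features(f, 1, 1, 8.0)
    assert v["absolute_distance_to_center"] == pytest.approx(10.0)
    assert v["polar_angle"] == pytest.approx(90.0)
    assert v["normalized_distance_to_center"] == pytest.approx(1.0)
    assert v["number_of_m_cells"] == 1
    assert v["number_of_s_cells"] == 1
    assert v["minimum_distance_to_m_cell"] == pytest.approx(20.0)
    assert v["number_of_m_cells_in_20um"] == 1
    assert v["number_of_m_cells_in_10um"] == 0
    # no hair cells: sentinel and flag
    assert v["average_distance_to_h_cell"] == pytest.approx(100.0)
    assert bool(v["missing_class_flag"])
    # founder: last division = recording start at own position
    assert v["time_to_last_division"] == pytest.approx(4.0)
    assert v["movement_distance_since_last_division"] == pytest.approx(0.0)
    assert v["movement_angle_to_last_division"] == pytest.approx(0.0)


def test_matches_brute_force_oracle_on_random_states(forests):
    """Equivalence with a naive double-loop recomputation to 1e-9 um."""
    rng = np.random.default_rng(42)
    config = FeatureConfig()
    checked = 0
    while checked < 100:
        f = forests[rng.integers(len(forests))]
        t = float(rng.choice(f.node(f.lineage_ids[0], 1).times))
        state_df = f.alive_at(t)
        if state_df.empty:
            continue
        i = int(rng.integers(len(state_df)))
        lid = int(state_df["lineage_id"].iloc[i])
        node = int(state_df["node_index"].iloc[i])
        got = extract_features(f, lid, node, t, config)

        state = list(
            state_df[["lineage_id", "node_index", "x_um", "y_um", "cell_class"]]
            .itertuples(index=False, name=None)
        )
        n = f.node(lid, node)
        if node == 1:
            last_div = (f.manifest.start_hpi, float(n.x[0]), float(n.y[0]))
        else:
            p = f.node(lid, node // 2)
            last_div = (p.end_time, float(p.x[-1]), float(p.y[-1]))
        info = {
            "time": t,
            "generation": n.generation,
            "founder_type": 1.0 if f.founder_class(lid) == "M" else 0.0,
            "n_founders": len(f.lineage_ids),
            "last_division": last_div,
        }
        expected = brute_force_features(state, (lid, node), (0.0, 0.0), config, info)
        for name in FEATURE_NAMES:
            assert got[name] == pytest.approx(expected[name], abs=1e-9), name
        checked += 1


def test_radius_counts_monotone_and_finite(division_features, clone_features):
    for table in (division_features, clone_features):
        assert np.isfinite(table[FEATURE_NAMES].to_numpy(float)).all()
        for cls in "hms":
            c10 = table[f"number_of_{cls}_cells_in_10um"]
            c20 = table[f"number_of_{cls}_cells_in_20um"]
            c30 = table[f"number_of_{cls}_cells_in_30um"]
            assert (c10 <= c20).all() and (c20 <= c30).all()
        assert table["normalized_distance_to_center"].between(0, 1).all()


def test_rotation_invariance_and_equivariance():
    rows = (
        cell_track(1, 1, 4.0, 10.0, "S", x=6.0, y=2.0)
        + cell_track(2, 1, 4.0, 10.0, "M", x=-3.0, y=8.0)
        + cell_track(3, 1, 4.0, 10.0, "H", x=0.5, y=-7.0)
    )
    f = build_forest(make_table(rows))
    base = extract_features(f, 1, 1, 8.0)

    angle = np.radians(137.0)
    R = np.array([[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]])
    rot_rows = []
    for lid, node, t, x, y, cls in rows:
        xr, yr = R @ np.array([x, y])
        rot_rows.append((lid, node, t, xr, yr, cls))
    fr = build_forest(make_table(rot_rows))
    rot = extract_features(fr, 1, 1, 8.0)

    invariant = [
        n
        for n in FEATURE_NAMES
        if n not in {"polar_angle", "x_coordinate", "y_coordinate"}
    ]
    for name in invariant:
        assert rot[name] == pytest.approx(base[name], abs=1e-9), name
    assert rot["polar_angle"] == pytest.approx((base["polar_angle"] + 137.0) % 360, abs=1e-6)


def test_clone_policy_rows_until_first_division(forests):
    table = build_feature_table(forests[:2], "clone")
    for entity, grp in table.groupby("entity_id"):
        exp, lid = entity.split(":")
        f = next(x for x in forests if x.experiment_id == exp)
        founder = f.founder(int(lid))
        assert len(grp) == len(founder.times)
        assert grp["label"].nunique() == 1


def test_division_policy_one_row_per_division(forests):
    table = build_feature_table(forests[:2], "division")
    assert (table.groupby("entity_id").size() == 1).all()
    # every row's time is the division time of its entity
    for row in table.itertuples(index=False):
        _, lid, node = row.entity_id.split(":")
        f = next(x for x in forests if x.experiment_id == row.experiment_id)
        assert f.node(int(lid), int(node)).end_time == pytest.approx(row.time_hpi)


def test_division_window_adds_preceding_frames(forests):
    t1 = build_feature_table(forests[:1], "division", division_window_frames=3)
    t3 = t1.groupby("entity_id").size()
    assert t3.max() == 3
    assert t3.min() >= 1  # founders dividing right away have shorter tracks


def test_empty_policy_errors():
    rows = cell_track(1, 1, 4.0, 30.0, "M")  # mantle founder only: no S rows
    f = build_forest(make_table(rows))
    with pytest.raises(ValueError, match="selected no rows"):
        build_feature_table(f, "clone")


def test_furthest_cell_normalization_subject_is_furthest():
    rows = (
        cell_track(1, 1, 4.0, 10.0, "S", x=12.0)
        + cell_track(2, 1, 4.0, 10.0, "S", x=3.0)
    )
    f = build_forest(make_table(rows))
    assert extract_features(f, 1, 1, 6.0)["normalized_distance_to_center"] == 1.0
    assert extract_features(f, 2, 1, 6.0)[
        "normalized_distance_to_center"
    ] == pytest.approx(0.25)
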