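"""Snapshots and sex-stratified nearest-neighbor distances (DAS/DSS/DDS)."""

import numpy as np
import pandas as pd
import pytest

from geosomtrack import neighbors
from conftest import make_fixes


def snap(members, time="2015-10-05 01:00"):
    df = pd.DataFrame(members, columns=["individual_id", "sex", "x", "y"])
    return neighbors.Snapshot(pd.Timestamp(time), df)


def test_snapshots_with_identical_times_contain_everyone():
    fixes = make_fixes([
        ("A", "F", "2015-10-05 01:00", 0, 0),
        ("B", "M", "2015-10-05 01:00", 10, 0),
        ("C", "F", "2015-10-05 01:00", 20, 0),
    ])
    snaps = neighbors.build_snapshots(fixes, tolerance=30)
    assert len(snaps) == 1
    assert set(snaps[0].members["individual_id"]) == {"A", "B", "C"}


def test_individual_beyond_tolerance_absent():
    fixes = make_fixes([
        ("A", "F", "2015-10-05 01:00", 0, 0),
        ("B", "M", "2015-10-05 01:45", 10, 0),
    ])
    snaps = neighbors.build_snapshots(fixes, tolerance=30)
    by_time = {s.snapshot_time: set(s.members["individual_id"]) for s in snaps}
    assert by_time[pd.Timestamp("2015-10-05 01:00")] == {"A"}
    assert by_time[pd.Timestamp("2015-10-05 02:00")] == {"B"}


def test_snapshot_membership_matches_brute_force():
    rng = np.random.default_rng(11)
    rows = []
    base = pd.Timestamp("2015-10-05 00:00")
    for ind, sex in [("A", "F"), ("B", "M"), ("C", "F")]:
        t = 0.0
        while t < 24:
            rows.append((ind, sex, str(base + pd.Timedelta(hours=t)),
                         float(rng.uniform(0, 100)), float(rng.uniform(0, 100))))
            t += rng.uniform(1, 2)
    fixes = make_fixes(rows)
    tol = pd.Timedelta(minutes=30)
    snaps = neighbors.build_snapshots(fixes, tolerance=30)
    for s in snaps:
        for ind, grp in fixes.groupby("individual_id"):
            deltas = (grp["timestamp"] - s.snapshot_time).abs()
            expect_present = deltas.min() <= tol
            present = ind in set(s.members["individual_id"])
            assert present == expect_present


def test_tolerance_must_be_positive(tiny_fixes):
    with pytest.raises(ValueError):
        neighbors.build_snapshots(tiny_fixes, tolerance=0)


def test_hand_computed_neighbor_distances():
    s = snap([("F1", "F", 0.0, 0.0), ("F2", "F", 3.0, 4.0),
              ("M1", "M", 0.0, 10.0)])
    rec = neighbors.neighbor_distances(s, "F1")
    assert rec["dss"] == pytest.approx(5.0)
    assert rec["dds"] == pytest.approx(10.0)
    assert rec["das"] == pytest.approx(5.0)
    assert rec["nearest_same"] == "F2"


def test_single_member_snapshot_all_missing():
    rec = neighbors.neighbor_distances(snap([("F1", "F", 0.0, 0.0)]), "F1")
    assert np.isnan(rec["das"]) and np.isnan(rec["dss"]) and np.isnan(rec["dds"])


def test_all_female_snapshot_dds_missing():
    rec = neighbors.neighbor_distances(
        snap([("F1", "F", 0, 0), ("F2", "F", 1, 0)]), "F1")
    assert np.isnan(rec["dds"])
    assert rec["das"] == rec["dss"]


def test_absent_target_rejected():
    with pytest.raises(ValueError, match="not in snapshot"):
        neighbors.neighbor_distances(snap([("F1", "F", 0, 0)]), "ZZ")


def test_nearest_tie_broken_by_lowest_id():
    s = snap([("F1", "F", 0, 0), ("F3", "F", 5, 0), ("F2", "F", -5, 0)])
    rec = neighbors.neighbor_distances(s, "F1")
    assert rec["nearest_same"] == "F2"


def test_das_is_min_of_dss_dds_and_matches_brute_force():
    rng = np.random.default_rng(5)
    for _ in range(50):
        n = rng.integers(2, 11)
        members = [(f"I{j}", "F" if rng.random() < 0.5 else "M",
                    float(rng.uniform(0, 1000)), float(rng.uniform(0, 1000)))
                   for j in range(n)]
        s = snap(members)
        ids = [m[0] for m in members]
        xy = np.array([(m[2], m[3]) for m in members])
        sexes = np.array([m[1] for m in members])
        dmat = np.hypot(xy[:, 0:1] - xy[:, 0], xy[:, 1:2] - xy[:, 1])
        np.fill_diagonal(dmat, np.inf)
        for i, tid in enumerate(ids):
            rec = neighbors.neighbor_distances(s, tid)
            assert rec["das"] == pytest.approx(dmat[i].min())
            same = dmat[i][sexes == sexes[i]]
            same = same[np.isfinite(same)]
            if len(same):
                assert rec["dss"] == pytest.approx(same.min())
            if not np.isnan(rec["dss"]) and not np.isnan(rec["dds"]):
                assert rec["das"] == pytest.approx(
                    min(rec["dss"], rec["dds"]))


def _records(n, n_missing, value=500.0, mean_target=400.0):
    rows = []
    for i in range(n):
        rows.append({"individual_id": "A", "sex": "F",
                     "snapshot_time": pd.Timestamp("2015-10-05") +
                     pd.Timedelta(hours=i),
                     "das": 1.0, "dss": np.nan if i < n_missing else mean_target,
                     "dds": 2.0})
    return pd.DataFrame(rows)


def test_impute_sparse_missing_with_individual_mean():
    rec = _records(100, 3)
    out = neighbors.impute_missing(rec)
    assert out["dss"].isna().sum() == 0
    assert np.allclose(out.loc[:2, "dss"], 400.0)
    assert out.loc[:2, "dss_imputed"].all()
    assert not out.loc[3:, "dss_imputed"].any()


def test_impute_no_missing_is_identity():
    rec = _records(50, 0)
    out = neighbors.impute_missing(rec)
    pd.testing.assert_frame_equal(
        out[["das", "dss", "dds"]], rec[["das", "dss", "dds"]])


def test_impute_skips_heavily_missing_variable():
    rec = _records(100, 10)   # 10% missing: above the 5% rule
    out = neighbors.impute_missing(rec)
    assert out["dss"].isna().sum() == 10
    assert not out["dss_imputed"].any()


def test_impute_never_touches_all_missing_variable():
    rec = _records(10, 10)
    out = neighbors.impute_missing(rec, max_missing_fraction=2.0)
    assert out["dss"].isna().all()


def test_eligibility_thresholds_straddled():
    rows = []
    for ind, sex, n in [("F1", "F", 60), ("F2", "F", 50),
                        ("M1", "M", 85), ("M2", "M", 70)]:
        for i in range(n):
            rows.append({"individual_id": ind, "sex": sex,
                         "snapshot_time": i, "das": 1.0,
                         "dss": 1.0, "dds": 1.0})
    rec = pd.DataFrame(rows)
    included, counts = neighbors.eligibility_filter(rec, 54, 80)
    assert included == {"F1", "M1"}


def test_eligibility_zero_thresholds_include_all():
    rec = _records(5, 0)
    included, _ = neighbors.eligibility_filter(rec, 0, 0)
    assert included == {"A"}


def test_eligibility_impossible_threshold_warns():
    rec = _records(5, 0)
    with pytest.warns(UserWarning, match="excluded every individual"):
        included, _ = neighbors.eligibility_filter(rec, 10_000, 10_000)
    assert included == set()
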