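"""Time-matched snapshots and sex-stratified nearest-neighbor distances.

For each snapshot (all individuals located at approximately the same time)
and each target individual, three nearest-neighbor distances are computed:

- DAS: distance to the nearest individual of any sex,
- DSS: distance to the nearest individual of the same sex,
- DDS: distance to the nearest individual of the different sex.

Whenever DSS and DDS both exist, DAS = min(DSS, DDS). Missing values (a
category empty in the snapshot) can be imputed by the individual's mean of
that variable, but only when the missing fraction is below a cap — the
convention for sparse gaps, not a general-purpose imputer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DISTANCE_VARS = ("das", "dss", "dds")


@dataclass(frozen=True)
class Snapshot:
    """Co-located fixes at one matched time: at most one member per individual."""
    snapshot_time: pd.Timestamp
    members: pd.DataFrame  # columns individual_id, sex, x, y

    def __post_init__(self) -> None:
        if self.members["individual_id"].duplicated().any():
            raise ValueError("duplicate individual in snapshot")


def build_snapshots(fixes: pd.DataFrame, tolerance: float = 30.0,
                    grid_minutes: float = 60.0) -> list[Snapshot]:
    """Group fixes of all individuals onto a common snapshot grid.

    Snapshot times are the union of fix times rounded to the nominal
    ``grid_minutes`` interval. Each individual contributes its temporally
    closest fix within ``±tolerance`` minutes of the snapshot time, or is
    absent. Empty snapshots are dropped.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    t = pd.DatetimeIndex(fixes["timestamp"])
    grid = t.round(f"{int(grid_minutes * 60)}s").unique().sort_values()

    tol = pd.Timedelta(minutes=tolerance)
    snapshots: list[Snapshot] = []
    # per individual, nearest fix per snapshot time via merge_asof
    per_ind = {
        ind: grp.sort_values("timestamp")
        for ind, grp in fixes.groupby("individual_id", sort=True)
    }
    grid_df = pd.DataFrame({"snapshot_time": grid})
    matches = []
    for ind, grp in per_ind.items():
        m = pd.merge_asof(
            grid_df, grp[["timestamp", "individual_id", "sex", "x", "y"]],
            left_on="snapshot_time", right_on="timestamp",
            direction="nearest", tolerance=tol)
        m = m.dropna(subset=["individual_id"])
        matches.append(m)
    allm = pd.concat(matches, ignore_index=True)
    for st, grp in allm.groupby("snapshot_time", sort=True):
        members = grp[["individual_id", "sex", "x", "y"]].reset_index(drop=True)
        snapshots.append(Snapshot(pd.Timestamp(st), members))
    return snapshots


def neighbor_distances(snapshot: Snapshot, target_id: str) -> dict:
    """DAS/DSS/DDS (and nearest-neighbor ids) for one target in one snapshot.

    Distances are planar Euclidean, self excluded; ties broken by lowest
    individual id. A category with no members yields NaN for that field.
    """
    mem = snapshot.members
    row = mem[mem["individual_id"] == target_id]
    if row.empty:
        raise ValueError(f"target {target_id!r} not in snapshot")
    tx, ty, tsex = row["x"].iloc[0], row["y"].iloc[0], row["sex"].iloc[0]
    others = mem[mem["individual_id"] != target_id]

    def nearest(sub: pd.DataFrame) -> tuple[float, str | None]:
        if sub.empty:
            return float("nan"), None
        d = np.hypot(sub["x"].to_numpy() - tx, sub["y"].to_numpy() - ty)
        order = np.lexsort((sub["individual_id"].to_numpy(), d))
        i = order[0]
        return float(d[i]), str(sub["individual_id"].iloc[i])

    das, das_id = nearest(others)
    dss, dss_id = nearest(others[others["sex"] == tsex])
    dds, dds_id = nearest(others[others["sex"] != tsex])
    return {
        "individual_id": target_id,
        "sex": tsex,
        "snapshot_time": snapshot.snapshot_time,
        "x": float(tx), "y": float(ty),
        "das": das, "dss": dss, "dds": dds,
        "nearest_any": das_id, "nearest_same": dss_id, "nearest_diff": dds_id,
    }


def neighbor_records(snapshots: list[Snapshot],
                     target_ids: list[str] | None = None) -> pd.DataFrame:
    """Long table of NeighborRecords over all snapshots and targets."""
    rows = []
    for snap in snapshots:
        ids = snap.members["individual_id"]
        for tid in ids if target_ids is None else ids[ids.isin(target_ids)]:
            rows.append(neighbor_distances(snap, tid))
    cols = ["individual_id", "sex", "snapshot_time", "x", "y",
            "das", "dss", "dds",
            "nearest_any", "nearest_same", "nearest_diff"]
    return pd.DataFrame(rows, columns=cols)


def impute_missing(records: pd.DataFrame,
                   max_missing_fraction: float = 0.05) -> pd.DataFrame:
    """Replace sparse missing distance values by the individual's mean.

    For each (individual, variable) with a missing fraction strictly below
    ``max_missing_fraction``, missing entries are filled with that
    individual's mean of the observed values; otherwise values are left
    missing and the rows are flagged. Adds ``<var>_imputed`` flag columns.
    """
    out = records.copy()
    for var in DISTANCE_VARS:
        out[f"{var}_imputed"] = False
    for ind, grp in records.groupby("individual_id", sort=False):
        for var in DISTANCE_VARS:
            vals = grp[var]
            n_missing = int(vals.isna().sum())
            if n_missing == 0:
                continue
            frac = n_missing / len(vals)
            if frac < max_missing_fraction and vals.notna().any():
                fill = float(vals.mean())
                idx = grp.index[vals.isna()]
                out.loc[idx, var] = fill
                out.loc[idx, f"{var}_imputed"] = True
    return out


def eligibility_filter(records: pd.DataFrame,
                       min_female: int = 54,
                       min_male: int = 80) -> tuple[set[str], pd.DataFrame]:
    """Individuals with enough records, using sex-specific thresholds.

    Returns the included id set and a per-individual count table with an
    ``included`` column. Emits a warning when nobody qualifies.
    """
    counts = (records.groupby(["individual_id", "sex"], sort=True)
              .size().rename("n").reset_index())
    thresh = counts["sex"].map({"F": min_female, "M": min_male})
    counts["included"] = counts["n"] >= thresh
    included = set(counts.loc[counts["included"], "individual_id"])
    if not included:
        import warnings
        warnings.warn("eligibility filter excluded every individual",
                      stacklevel=2)
    return included, counts
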