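"""Dyadic co-occurrence detection, monthly profiles, radius sweep, and the
stable-radius selection rule.

A co-occurrence event is an unordered pair of individuals located within a
radius of each other in one time-matched snapshot, classed FF, FM or MM by
the members' sexes. Dyads, not cliques: three mutually close individuals
yield three events. A pair present in several snapshots counts once per
snapshot (frequencies are observation-weighted).

The working radius is chosen by sweeping radii and finding where the
month-by-class incidence pattern first changes relative to the smallest
radius: the largest radius whose support set (cells with nonzero frequency)
still equals the base radius's support. This is a quantitative surrogate
for choosing the radius by eye from sweep plots.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .neighbors import Snapshot

PAIR_CLASSES = ("FF", "FM", "MM")


def _pair_class(sex_a: str, sex_b: str) -> str:
    return "".join(sorted(sex_a + sex_b))


def detect(snapshots: list[Snapshot], radius: float,
           month_of: dict | None = None) -> pd.DataFrame:
    """All within-radius pairs across snapshots.

    Parameters
    ----------
    snapshots
        Time-matched snapshots (see `neighbors.build_snapshots`).
    radius
        Maximum pair distance in meters (inclusive).
    month_of
        Optional mapping snapshot_time -> month index; defaults to the
        calendar month of the snapshot time.

    Returns
    -------
    DataFrame with columns ``snapshot_time, month_index, id_a, id_b,
    pair_class, distance, radius`` and ``id_a < id_b``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    rows = []
    for snap in snapshots:
        mem = snap.members
        if len(mem) < 2:
            continue
        xy = mem[["x", "y"]].to_numpy(dtype=float)
        tree = cKDTree(xy)
        pairs = tree.query_pairs(r=radius, output_type="ndarray")
        if len(pairs) == 0:
            continue
        ids = mem["individual_id"].to_numpy()
        sexes = mem["sex"].to_numpy()
        month = (month_of[snap.snapshot_time] if month_of is not None
                 else snap.snapshot_time.month)
        d = np.hypot(*(xy[pairs[:, 0]] - xy[pairs[:, 1]]).T)
        for (i, j), dist in zip(pairs, d):
            a, b = sorted((str(ids[i]), str(ids[j])))
            rows.append({
                "snapshot_time": snap.snapshot_time,
                "month_index": int(month),
                "id_a": a, "id_b": b,
                "pair_class": _pair_class(sexes[i], sexes[j]),
                "distance": float(dist),
                "radius": float(radius),
            })
    cols = ["snapshot_time", "month_index", "id_a", "id_b", "pair_class",
            "distance", "radius"]
    return pd.DataFrame(rows, columns=cols)


def monthly_profile(events: pd.DataFrame, radius: float,
                    months: range = range(1, 13)) -> pd.DataFrame:
    """Within-month relative frequencies of FF/FM/MM events at one radius.

    ``rel_freq(class, month) = events of class that month / total events
    that month``; months with no events report zeros for every class.
    """
    if len(events) and not np.allclose(events["radius"], radius):
        raise ValueError("events mix radii; profile requires a single radius")
    rows = []
    by_month = events.groupby("month_index") if len(events) else {}
    counts = {m: {c: 0 for c in PAIR_CLASSES} for m in months}
    if len(events):
        for (m, c), grp in events.groupby(["month_index", "pair_class"]):
            if m in counts:
                counts[m][c] = len(grp)
    for m in months:
        total = sum(counts[m].values())
        for c in PAIR_CLASSES:
            rows.append({
                "radius": float(radius), "month_index": m, "pair_class": c,
                "count": counts[m][c],
                "rel_freq": counts[m][c] / total if total else 0.0,
            })
    return pd.DataFrame(rows)


def radius_sweep(snapshots: list[Snapshot],
                 radii: np.ndarray | None = None,
                 month_of: dict | None = None,
                 months: range = range(1, 13)) -> pd.DataFrame:
    """Monthly profiles across a sorted ladder of radii (default 50..2000 by 50)."""
    if radii is None:
        radii = np.arange(50.0, 2000.0 + 1, 50.0)
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0) or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be positive and strictly increasing")
    # one detect pass at the largest radius, then filter by distance
    events_max = detect(snapshots, float(radii[-1]), month_of=month_of)
    profiles = []
    for r in radii:
        ev = events_max[events_max["distance"] <= r].copy()
        ev["radius"] = float(r)
        profiles.append(monthly_profile(ev, float(r), months=months))
    return pd.concat(profiles, ignore_index=True)


def stable_radius(profiles: pd.DataFrame, base_radius: float = 50.0) -> float:
    """Largest radius whose incidence support matches the base radius.

    The support of a radius is the set of (month, pair_class) cells with
    nonzero frequency. Walking up the sorted radii, the first radius whose
    support differs from the base support ends the stable range; the radius
    just below it is returned (the base radius itself if the support changes
    immediately).
    """
    radii = np.sort(profiles["radius"].unique())
    if base_radius not in radii:
        raise ValueError(f"base radius {base_radius} not in sweep")

    def support(r: float) -> frozenset:
        sub = profiles[(profiles["radius"] == r) & (profiles["rel_freq"] > 0)]
        return frozenset(zip(sub["month_index"], sub["pair_class"]))

    base = support(base_radius)
    stable = base_radius
    for r in radii[radii > base_radius]:
        if support(r) != base:
            break
        stable = r
    return float(stable)
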