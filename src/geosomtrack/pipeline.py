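"""End-to-end workflow: fixes -> movement stats -> snapshots -> neighbor
distances -> co-occurrence sweep -> Geo-SOM trainings -> clustering and
plane-association scoring, with a run manifest and figure output.

Three maps are trained: one with females as the target individuals, one
with males, and one over everyone. Each map sees, per record, the planar
position (X, Y; the geographic variables), water temperature (WT), the 8
habitat indicators, the sex code (SR), movement covariates (LiS, AnS),
the three nearest-neighbor distances (DAS, DSS, DDS), and the per-class
co-occurrence incidence at the working radius (FM, FF, MM). All variables
are min-max normalized to [0, 1] before training.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, cooccur, geosom, io, movement, neighbors

GEO_VARS = ("X", "Y")
FEATURE_VARS = ("X", "Y", "WT") + io.HABITAT_LABELS + (
    "SR", "LiS", "AnS", "DAS", "DSS", "DDS", "FM", "FF", "MM")


@dataclass(frozen=True)
class PipelineConfig:
    """Settings of the full analysis; defaults are the reference settings."""
    seed: int = 0
    snapshot_tolerance_min: float = 30.0
    max_gap_hours: float = 3.0
    radii: tuple[float, ...] = tuple(np.arange(50.0, 2001.0, 50.0))
    base_radius: float = 50.0
    working_radius: float = 250.0       # radius for events fed to training
    grid_rows: int = 9
    grid_cols: int = 6
    geo_k: int = 3
    phases: tuple[geosom.TrainingPhase, ...] = geosom.REFERENCE_PHASES
    kmeans_range: tuple[int, int] = (2, 10)
    kmeans_restarts: int = 20
    min_female_records: int = 54
    min_male_records: int = 80
    max_missing_fraction: float = 0.05
    round_start_month: int = 10

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["phases"] = [dataclasses.asdict(p) for p in self.phases]
        d["radii"] = list(self.radii)
        return d


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def month_map(snapshots, round_start_month: int = 10) -> dict:
    """snapshot_time -> survey round (calendar month, start month = round 1)."""
    return {s.snapshot_time:
            ((s.snapshot_time.month - round_start_month) % 12) + 1
            for s in snapshots}


def build_feature_table(fixes: pd.DataFrame, hmap: io.HabitatMap,
                        temps: pd.DataFrame,
                        config: PipelineConfig) -> tuple[pd.DataFrame, dict]:
    """One row per (eligible individual x snapshot) with all map variables.

    Missing movement covariates (no retained step near the snapshot) are
    filled with the individual's mean; missing neighbor distances follow
    the sparse-imputation rule and rows still missing afterwards are
    dropped. Returns the table plus stage bookkeeping (row counts etc.).
    """
    log: dict = {}
    steps = movement.compute_steps_all(fixes, max_gap=config.max_gap_hours)
    log["n_steps"] = len(steps)

    snaps = neighbors.build_snapshots(
        fixes, tolerance=config.snapshot_tolerance_min)
    log["n_snapshots"] = len(snaps)
    records = neighbors.neighbor_records(snaps)
    log["n_neighbor_records"] = len(records)

    records = neighbors.impute_missing(
        records, max_missing_fraction=config.max_missing_fraction)
    eligible, counts = neighbors.eligibility_filter(
        records, config.min_female_records, config.min_male_records)
    log["n_eligible"] = len(eligible)
    log["eligibility"] = counts

    months = month_map(snaps, config.round_start_month)
    events = cooccur.detect(snaps, config.working_radius, month_of=months)
    log["n_events_working_radius"] = len(events)

    feat = records[records["individual_id"].isin(eligible)].copy()
    feat["survey_round"] = feat["snapshot_time"].map(months)
    feat = feat.rename(columns={"x": "X", "y": "Y", "das": "DAS",
                                "dss": "DSS", "dds": "DDS"})
    # habitat indicators + temperature at the member position
    annotated = io.annotate_habitat(
        feat.rename(columns={"X": "x", "Y": "y"}), hmap)
    for lab in io.HABITAT_LABELS:
        feat[lab] = annotated[lab].to_numpy()
    feat = io.attach_temperature(feat, temps).rename(columns={"wt": "WT"})
    feat["SR"] = feat["sex"].map({"F": 1.0, "M": -1.0})

    # movement covariates: nearest step ending within the snapshot tolerance
    tol = pd.Timedelta(minutes=config.snapshot_tolerance_min)
    mov_parts = []
    for ind, grp in feat.groupby("individual_id", sort=True):
        st = steps[steps["individual_id"] == ind]
        base = grp[["snapshot_time"]].sort_values("snapshot_time")
        if len(st):
            m = pd.merge_asof(
                base, st[["t1", "linear_speed", "angular_speed"]]
                .sort_values("t1"),
                left_on="snapshot_time", right_on="t1",
                direction="nearest", tolerance=tol)
        else:
            m = base.assign(linear_speed=np.nan, angular_speed=np.nan)
        m["individual_id"] = ind
        mov_parts.append(m[["individual_id", "snapshot_time",
                            "linear_speed", "angular_speed"]])
    mov = pd.concat(mov_parts, ignore_index=True)
    feat = feat.merge(mov, on=["individual_id", "snapshot_time"], how="left")
    feat = feat.rename(columns={"linear_speed": "LiS",
                                "angular_speed": "AnS"})
    for var in ("LiS", "AnS"):
        ind_mean = feat.groupby("individual_id")[var].transform("mean")
        feat[var] = feat[var].fillna(ind_mean).fillna(feat[var].mean())

    # per-class co-occurrence incidence at the working radius: the number
    # of partners of each class co-located with the individual in that
    # snapshot (log-compressed)
    inc = _incidence(events, feat)
    feat = feat.merge(inc, on=["individual_id", "snapshot_time"], how="left")
    for c in cooccur.PAIR_CLASSES:
        # log1p: incidence counts are heavy-tailed; without the compression
        # a single busy snapshot pins the min-max normalization
        feat[c] = np.log1p(feat[c].fillna(0.0))

    before = len(feat)
    feat = feat.dropna(subset=["DAS", "DSS", "DDS"]).reset_index(drop=True)
    log["n_rows_dropped_missing"] = before - len(feat)
    log["n_feature_rows"] = len(feat)
    return feat, log


def _incidence(events: pd.DataFrame, records: pd.DataFrame) -> pd.DataFrame:
    """Per (individual, snapshot) co-occurrence partner counts by class."""
    base = records[["individual_id", "snapshot_time"]].copy()
    if not len(events):
        for c in cooccur.PAIR_CLASSES:
            base[c] = 0.0
        return base
    half = pd.concat([
        events.rename(columns={"id_a": "individual_id"})[
            ["individual_id", "snapshot_time", "pair_class"]],
        events.rename(columns={"id_b": "individual_id"})[
            ["individual_id", "snapshot_time", "pair_class"]],
    ])
    counts = (half.groupby(["individual_id", "snapshot_time", "pair_class"])
              .size().unstack(fill_value=0).reset_index())
    for c in cooccur.PAIR_CLASSES:
        if c not in counts.columns:
            counts[c] = 0
    out = base.merge(counts, on=["individual_id", "snapshot_time"],
                     how="left")
    for c in cooccur.PAIR_CLASSES:
        out[c] = out[c].fillna(0.0)
    return out[["individual_id", "snapshot_time", *cooccur.PAIR_CLASSES]]


def train_map(feat: pd.DataFrame, config: PipelineConfig,
              target: str = "all"
              ) -> tuple[geosom.SomGrid, geosom.MinMaxNormalizer,
                         np.ndarray, pd.DataFrame, list[float]]:
    """Train one Geo-SOM on the feature rows of the given target sex.

    Returns (trained grid, normalizer, normalized samples, the feature rows
    used, quantization-error history).
    """
    sub = feat if target == "all" else feat[feat["sex"] == target]
    sub = sub.reset_index(drop=True)
    if not len(sub):
        raise ValueError(f"no feature rows for target {target!r}")
    raw = sub[list(FEATURE_VARS)].to_numpy(dtype=float)
    norm = geosom.MinMaxNormalizer().fit(raw)
    samples = norm.transform(raw)
    grid = geosom.init_grid(config.grid_rows, config.grid_cols,
                            FEATURE_VARS, GEO_VARS, seed=config.seed)
    tol = geosom.GeoTolerance(config.geo_k)
    trained, qe = geosom.train(grid, samples, phases=config.phases,
                               tolerance=tol, seed=config.seed)
    return trained, norm, samples, sub, qe


def run_all(fixes: pd.DataFrame, hmap: io.HabitatMap, temps: pd.DataFrame,
            config: PipelineConfig, outdir: Path,
            make_figures: bool = True) -> dict:
    """Full analysis; writes CSV/JSON outputs and returns a result dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    manifest = {
        "config": config.to_dict(),
        "n_input_fixes": len(fixes),
        "stages": {},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))

    # movement
    steps = movement.compute_steps_all(fixes, max_gap=config.max_gap_hours)
    summary = movement.movement_summary(steps)
    steps.to_csv(outdir / "steps.csv", index=False)
    (outdir / "movement_summary.json").write_text(
        json.dumps(summary, indent=1))

    # co-occurrence sweep and stable radius
    snaps = neighbors.build_snapshots(
        fixes, tolerance=config.snapshot_tolerance_min)
    months = month_map(snaps, config.round_start_month)
    profiles = cooccur.radius_sweep(snaps, np.array(config.radii),
                                    month_of=months)
    profiles.to_csv(outdir / "cooccurrence_sweep.csv", index=False)
    stable = cooccur.stable_radius(profiles, config.base_radius)
    events = cooccur.detect(snaps, config.working_radius, month_of=months)
    events.to_csv(outdir / "cooccurrence_events.csv", index=False)

    # features + three trainings
    feat, log = build_feature_table(fixes, hmap, temps, config)
    log["eligibility"].to_csv(outdir / "eligibility.csv", index=False)
    feat_out = feat.drop(columns=[c for c in ("nearest_any", "nearest_same",
                                              "nearest_diff")
                                  if c in feat.columns])
    feat_out.to_csv(outdir / "features.csv", index=False)

    maps: dict[str, dict] = {}
    for target in ("F", "M", "all"):
        trained, norm, samples, sub, qe = train_map(feat, config, target)
        tolg = geosom.GeoTolerance(config.geo_k)
        geosom.save_model(outdir / f"geosom_{target}.json", trained, norm,
                          tolg, meta={"target": target, "qe_initial": qe[0],
                                      "qe_final": qe[-1]})
        planes = geosom.component_planes(trained)
        _planes_csv(planes, trained, outdir / f"planes_{target}.csv")
        maps[target] = {"grid": trained, "norm": norm, "samples": samples,
                        "rows": sub, "qe": qe, "planes": planes}

    # clustering + stats on the all-individuals map
    allm = maps["all"]
    result = analysis.kmeans_codebook(
        allm["grid"], range(config.kmeans_range[0], config.kmeans_range[1] + 1),
        seed=config.seed, restarts=config.kmeans_restarts)
    rc = allm["grid"].node_rc()
    pd.DataFrame({"node_row": rc[:, 0], "node_col": rc[:, 1],
                  "cluster": result.labels}).to_csv(
        outdir / "clusters.csv", index=False)
    tolg = geosom.GeoTolerance(config.geo_k)
    stats_df = analysis.cluster_distance_stats(
        result, allm["grid"], allm["samples"], allm["rows"],
        variables=("DAS", "DSS", "DDS"), tolerance=tolg)
    stats_df.to_csv(outdir / "cluster_stats.csv", index=False)
    bmus = geosom.map_samples(allm["grid"], allm["samples"], tolg)
    clusters_per_sample = result.labels[bmus]
    pvals = analysis.compare_clusters(
        allm["rows"]["DDS"].to_numpy(dtype=float), clusters_per_sample)
    pvals.to_csv(outdir / "cluster_pvalues.csv", index=False)

    # association rows follow the per-target-sex trainings: different-sex
    # and F-F rows from the females-as-targets map, M-F and M-M rows from
    # the males-as-targets map
    assoc_parts = []
    for target, classes in (("F", ("FM", "FF")), ("M", ("FM", "MM"))):
        part = analysis.association_table(maps[target]["planes"],
                                          pair_classes=classes)
        part.insert(0, "target_sex", target)
        assoc_parts.append(part)
    assoc = pd.concat(assoc_parts, ignore_index=True)
    assoc.to_csv(outdir / "association_table.csv", index=False)

    if make_figures:
        _figures(outdir, maps["all"], profiles)

    manifest["stages"] = {
        "movement": summary,
        "snapshots": {"n": len(snaps)},
        "cooccurrence": {"stable_radius_m": stable,
                         "working_radius_m": config.working_radius,
                         "n_events": len(events)},
        "features": {k: v for k, v in log.items() if k != "eligibility"},
        "training": {t: {"qe_initial": maps[t]["qe"][0],
                         "qe_final": maps[t]["qe"][-1],
                         "n_samples": len(maps[t]["rows"])}
                     for t in maps},
        "clustering": {"k": result.n_clusters,
                       "db_scores": result.selection_scores},
        "wall_seconds": time.time() - t_start,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return {"summary": summary, "stable_radius": stable, "feat": feat,
            "maps": maps, "clusters": result, "cluster_stats": stats_df,
            "pvalues": pvals, "association": assoc, "profiles": profiles}


def _planes_csv(planes: dict, grid: geosom.SomGrid, path: Path) -> None:
    rc = grid.node_rc()
    rows = []
    for var, vals in planes.items():
        for n in range(grid.n_nodes):
            rows.append({"node_row": rc[n, 0], "node_col": rc[n, 1],
                         "variable": var, "value": vals[n]})
    pd.DataFrame(rows).to_csv(path, index=False)


def _figures(outdir: Path, allmap: dict, profiles: pd.DataFrame) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    grid = allmap["grid"]
    planes = allmap["planes"]
    n = len(planes)
    ncols = 5
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(nrows, ncols, figsize=(2.2 * ncols, 2.2 * nrows))
    for ax, (var, vals) in zip(np.ravel(axes), planes.items()):
        ax.imshow(vals.reshape(grid.rows, grid.cols), vmin=0, vmax=1,
                  cmap="viridis")
        ax.set_title(var, fontsize=8)
        ax.set_xticks([])
        ax.set_yticks([])
    for ax in np.ravel(axes)[n:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(outdir / "component_planes.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    tot = (profiles.groupby(["radius", "pair_class"])["count"].sum()
           .unstack(fill_value=0))
    tot.plot(ax=ax)
    ax.set_xlabel("radius (m)")
    ax.set_ylabel("events")
    fig.tight_layout()
    fig.savefig(outdir / "radius_sweep.png", dpi=120)
    plt.close(fig)
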