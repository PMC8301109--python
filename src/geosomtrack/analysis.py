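"""Post-training analysis of a trained map: k-means clustering of the
codebook, per-cluster distance statistics with pairwise tests, the
sex-ratio variable, and quantitative component-plane association scoring.

Plane association replaces visual matching of component maps with a
rank-correlation score over nodes plus a decile-overlap measure: two planes
"match" when high nodes coincide (positive Spearman), and are "inverse"
when one plane's peaks sit on the other's troughs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import davies_bouldin_score
from statsmodels.stats.multitest import multipletests

from .geosom import SomGrid, GeoTolerance, map_samples


@dataclass
class ClusterResult:
    n_clusters: int
    labels: np.ndarray              # per-node cluster label
    selection_scores: dict[int, float]  # candidate k -> Davies-Bouldin index


@dataclass(frozen=True)
class SexRatio:
    """Group sex composition: mean of codes +1 (female) / -1 (male)."""
    sr_raw: float    # in [-1, 1]; +1 all female
    sr_norm: float   # (sr_raw + 1) / 2; 0.5 = equal counts


@dataclass(frozen=True)
class AssociationScore:
    plane_a: str
    plane_b: str
    score: float             # Spearman rank correlation over nodes
    polarity: str            # "match" (score >= 0) or "inverse"
    extremum_overlap: float  # Jaccard of top-decile vs top/bottom-decile nodes
    defined: bool = True     # False when a plane is constant


def kmeans_codebook(grid: SomGrid, k_range=range(2, 11), seed: int = 0,
                    restarts: int = 20) -> ClusterResult:
    """Cluster the node weight vectors; pick k by the Davies-Bouldin index.

    Best-of-``restarts`` k-means per candidate k; the selected k minimizes
    the Davies-Bouldin index (lower = tighter, better-separated clusters).
    Deterministic given the seed.
    """
    ks = [k for k in k_range]
    if min(ks) < 2:
        raise ValueError("minimum candidate k is 2")
    if max(ks) > grid.n_nodes:
        raise ValueError("k_range exceeds node count")
    scores: dict[int, float] = {}
    fits: dict[int, np.ndarray] = {}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
        labels = km.fit_predict(grid.weights)
        if len(np.unique(labels)) < 2:
            continue
        scores[k] = float(davies_bouldin_score(grid.weights, labels))
        fits[k] = labels
    best_k = min(scores, key=lambda k: (scores[k], k))
    return ClusterResult(best_k, fits[best_k], scores)


def cluster_distance_stats(result: ClusterResult, grid: SomGrid,
                           samples: np.ndarray, sample_table: pd.DataFrame,
                           variables=("das", "dss", "dds"),
                           tolerance: GeoTolerance | None = None
                           ) -> pd.DataFrame:
    """Mean, SD and n per (cluster x variable) over samples mapped via BMU.

    ``sample_table`` holds the raw-unit variables aligned row-for-row with
    the normalized ``samples`` used for mapping. Also flags the clusters
    with minimum and maximum mean different-sex distance (dds), the
    convention for naming the close-contact and wide-spacing groups.
    """
    bmus = map_samples(grid, samples, tolerance)
    clusters = result.labels[bmus]
    rows = []
    for c in range(result.n_clusters):
        in_c = clusters == c
        for var in variables:
            vals = sample_table.loc[in_c, var].dropna()
            rows.append({
                "cluster": c, "variable": var, "n": int(len(vals)),
                "mean": float(vals.mean()) if len(vals) else float("nan"),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
            })
    out = pd.DataFrame(rows)
    dds_name = next((v for v in variables if v.lower() == "dds"), None)
    if dds_name is not None:
        dds = out[out["variable"] == dds_name].dropna(subset=["mean"])
        if len(dds):
            out.attrs["min_distance_cluster"] = int(
                dds.loc[dds["mean"].idxmin(), "cluster"])
            out.attrs["max_distance_cluster"] = int(
                dds.loc[dds["mean"].idxmax(), "cluster"])
    return out


def compare_clusters(values: np.ndarray, groups: np.ndarray) -> pd.DataFrame:
    """Pairwise Welch t-tests across groups with Holm correction.

    Groups with fewer than 2 observations are skipped and flagged. Returns
    one row per pair with raw and Holm-adjusted p-values.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    rows = []
    for i, a in enumerate(uniq):
        for b in uniq[i + 1:]:
            va = values[(groups == a) & np.isfinite(values)]
            vb = values[(groups == b) & np.isfinite(values)]
            if len(va) < 2 or len(vb) < 2:
                rows.append({"group_a": a, "group_b": b, "p_raw": np.nan,
                             "skipped": True})
                continue
            t = stats.ttest_ind(va, vb, equal_var=False)
            rows.append({"group_a": a, "group_b": b,
                         "p_raw": float(t.pvalue), "skipped": False})
    out = pd.DataFrame(rows)
    tested = ~out["skipped"]
    out["p_adj"] = np.nan
    if tested.any():
        out.loc[tested, "p_adj"] = multipletests(
            out.loc[tested, "p_raw"], method="holm")[1]
    return out


def sex_ratio(sexes) -> SexRatio:
    """Sex ratio of a group: codes +1 for F, -1 for M, averaged."""
    sexes = list(sexes)
    if not sexes:
        raise ValueError("empty member list")
    codes = [{"F": 1.0, "M": -1.0}[s] for s in sexes]
    raw = float(np.mean(codes))
    return SexRatio(sr_raw=raw, sr_norm=(raw + 1.0) / 2.0)


def _decile_set(plane: np.ndarray, decile: float, top: bool) -> set[int]:
    n = max(1, int(round(decile * len(plane))))
    order = np.argsort(plane, kind="stable")
    return set((order[::-1] if top else order)[:n].tolist())


def plane_association(plane_a: np.ndarray, plane_b: np.ndarray,
                      name_a: str = "a", name_b: str = "b",
                      decile: float = 0.1) -> AssociationScore:
    """Spearman rank correlation of two component planes over nodes.

    Polarity is "inverse" for negative scores; the extremum overlap is the
    Jaccard index between plane A's top-decile node set and plane B's top
    (match) or bottom (inverse) decile.
    """
    a = np.asarray(plane_a, dtype=float)
    b = np.asarray(plane_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("planes cover different grids")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return AssociationScore(name_a, name_b, float("nan"), "match",
                                float("nan"), defined=False)
    rho = float(stats.spearmanr(a, b).statistic)
    polarity = "inverse" if rho < 0 else "match"
    top_a = _decile_set(a, decile, top=True)
    ext_b = _decile_set(b, decile, top=(polarity == "match"))
    overlap = len(top_a & ext_b) / len(top_a | ext_b)
    return AssociationScore(name_a, name_b, rho, polarity, float(overlap))


def association_table(planes: dict[str, np.ndarray],
                      pair_classes=("FM", "FF", "MM"),
                      habitat_variables=("TG", "FL", "XHV", "HHV", "HWV",
                                         "OA", "R", "AS"),
                      threshold: float = 0.0) -> pd.DataFrame:
    """Count matrix of habitat planes positively associated with each
    pair-class incidence plane (association score above ``threshold``).

    A reproducible stand-in for tallying matched component maps by eye:
    cell (class, habitat) is 1 when the Spearman score of the two planes
    exceeds the threshold, with the score reported alongside.
    """
    rows = []
    for pc in pair_classes:
        if pc not in planes:
            continue
        for hv in habitat_variables:
            if hv not in planes:
                continue
            sc = plane_association(planes[pc], planes[hv], pc, hv)
            rows.append({
                "pair_class": pc, "habitat": hv,
                "score": sc.score,
                "associated": int(sc.defined and sc.score > threshold),
            })
    return pd.DataFrame(rows)
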