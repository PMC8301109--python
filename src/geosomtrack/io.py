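"""Reading, writing and validation of telemetry fix tables, habitat maps
and water-temperature tables.

The planar frame is meters. Habitat maps are GeoJSON FeatureCollections of
labeled polygons; fix tables and temperature tables are plain CSV. A small
helper projects lon/lat onto a local equirectangular plane about the data
centroid, which is adequate for a site a few kilometers across.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, shape, mapping

#: Vegetation labels: hydric herbaceous vegetation, tall grassland, xeric
#: herbaceous vegetation, hydric woody vegetation, floating-leaved hydrophytes.
VEGETATION_LABELS = ("HHV", "TG", "XHV", "HWV", "FL")
#: Land-cover labels: open area, road, artificial structure.
LANDCOVER_LABELS = ("OA", "R", "AS")
HABITAT_LABELS = VEGETATION_LABELS + LANDCOVER_LABELS

FIX_COLUMNS = ["individual_id", "sex", "timestamp", "x", "y", "survey_round"]


class SchemaError(ValueError):
    """A required column or field is missing or malformed."""


class DataError(ValueError):
    """Row-level content violates an invariant (duplicates, bad values)."""


@dataclass(frozen=True)
class HabitatMap:
    """Labeled habitat polygons on a planar frame.

    Patches carry one label from the fixed 8-member vocabulary. Vegetation
    patches never overlap each other; a vegetation patch may overlap a
    land-cover patch (e.g. an open area crossing grassland).
    """

    patches: tuple[tuple[str, Polygon], ...]

    def __post_init__(self) -> None:
        for label, poly in self.patches:
            if label not in HABITAT_LABELS:
                raise SchemaError(f"unknown habitat label {label!r}")
            if not poly.is_valid:
                raise DataError(f"invalid (self-intersecting?) polygon for {label}")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) over all patches."""
        bounds = np.array([p.bounds for _, p in self.patches])
        return (bounds[:, 0].min(), bounds[:, 1].min(),
                bounds[:, 2].max(), bounds[:, 3].max())

    def labels_present(self) -> set[str]:
        return {label for label, _ in self.patches}


def read_fixes(path, dialect: Mapping[str, str] | None = None,
               round_start_month: int = 10) -> pd.DataFrame:
    """Read a telemetry fix CSV into the canonical fix table.

    Parameters
    ----------
    path
        CSV with at least columns ``id, sex, timestamp, x, y`` (an optional
        ``round`` column overrides the derived survey round).
    dialect
        Optional mapping from canonical names (``id``, ``sex``, ``timestamp``,
        ``x``, ``y``, ``round``) to the file's column names.
    round_start_month
        Calendar month mapped to survey round 1 (default October).

    Returns
    -------
    DataFrame with columns ``individual_id, sex, timestamp, x, y,
    survey_round``, sorted by (individual_id, timestamp).
    """
    raw = pd.read_csv(path, dtype={"sex": str})
    names = {"id": "id", "sex": "sex", "timestamp": "timestamp",
             "x": "x", "y": "y", "round": "round"}
    if dialect:
        names.update(dialect)
    for key in ("id", "sex", "timestamp", "x", "y"):
        if names[key] not in raw.columns:
            raise SchemaError(f"missing required column {names[key]!r}")

    ts = pd.to_datetime(raw[names["timestamp"]], errors="coerce", utc=True)
    bad = ts.isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise DataError(
            f"unparseable timestamp {raw[names['timestamp']][bad].iloc[0]!r} "
            f"at line {line}")
    fixes = pd.DataFrame({
        "individual_id": raw[names["id"]].astype(str),
        "sex": raw[names["sex"]].astype(str).str.upper(),
        # tz-naive UTC internally
        "timestamp": ts.dt.tz_convert("UTC").dt.tz_localize(None),
        "x": pd.to_numeric(raw[names["x"]]),
        "y": pd.to_numeric(raw[names["y"]]),
    })
    if not fixes["sex"].isin(["F", "M"]).all():
        offending = sorted(set(fixes["sex"]) - {"F", "M"})
        raise DataError(f"sex must be F or M; found {offending}")
    if not (np.isfinite(fixes["x"]).all() and np.isfinite(fixes["y"]).all()):
        raise DataError("non-finite coordinates")

    dup = fixes.duplicated(subset=["individual_id", "timestamp"], keep=False)
    if dup.any():
        keys = fixes.loc[dup, ["individual_id", "timestamp"]].drop_duplicates()
        raise DataError(
            "duplicate (id, timestamp) rows: "
            + "; ".join(f"({r.individual_id}, {r.timestamp})"
                        for r in keys.itertuples()))

    if names["round"] in raw.columns:
        fixes["survey_round"] = raw[names["round"]].astype(int)
    else:
        fixes["survey_round"] = survey_round_of(fixes["timestamp"],
                                                round_start_month)
    fixes = fixes.sort_values(["individual_id", "timestamp"],
                              kind="stable").reset_index(drop=True)
    return fixes


def survey_round_of(timestamps: pd.Series, round_start_month: int = 10) -> pd.Series:
    """Survey round 1..12 from the calendar month (start month -> 1)."""
    month = pd.DatetimeIndex(timestamps).month
    return pd.Series(((month - round_start_month) % 12) + 1,
                     index=timestamps.index, dtype=int)


def write_fixes(fixes: pd.DataFrame, path) -> None:
    """Write the canonical fix table in the CSV dialect `read_fixes` accepts."""
    out = pd.DataFrame({
        "id": fixes["individual_id"],
        "sex": fixes["sex"],
        "timestamp": fixes["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S"),
        "x": fixes["x"],
        "y": fixes["y"],
        "round": fixes["survey_round"],
    })
    out.to_csv(path, index=False)


def read_habitat_map(path) -> HabitatMap:
    """Read a GeoJSON FeatureCollection; each Feature needs a "label" property."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise SchemaError("habitat map must be a GeoJSON FeatureCollection")
    patches = []
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        if "label" not in props:
            raise SchemaError("habitat Feature missing 'label' property")
        geom = shape(feat["geometry"])
        if geom.geom_type != "Polygon":
            raise SchemaError(f"habitat geometry must be Polygon, got {geom.geom_type}")
        patches.append((props["label"], geom))
    return HabitatMap(tuple(patches))


def write_habitat_map(hmap: HabitatMap, path) -> None:
    features = [
        {"type": "Feature", "properties": {"label": label},
         "geometry": mapping(poly)}
        for label, poly in hmap.patches
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_temperatures(path) -> pd.DataFrame:
    """Read a monthly water-temperature CSV with columns ``month, wt``."""
    raw = pd.read_csv(path)
    for col in ("month", "wt"):
        if col not in raw.columns:
            raise SchemaError(f"missing required column {col!r}")
    temps = raw[["month", "wt"]].astype({"month": int, "wt": float})
    if temps["month"].duplicated().any():
        raise DataError("duplicate month in temperature table")
    return temps.sort_values("month").reset_index(drop=True)


def write_temperatures(temps: pd.DataFrame, path) -> None:
    temps[["month", "wt"]].to_csv(path, index=False)


def annotate_habitat(fixes: pd.DataFrame, hmap: HabitatMap) -> pd.DataFrame:
    """Add one 0/1 point-in-polygon indicator column per habitat label.

    Boundary points count as inside. If a point falls on the shared boundary
    of two patches with the same vocabulary class (the only way two
    vegetation patches can both contain it), the earliest patch in map order
    wins, keeping each class's indicators summing to at most 1.
    """
    out = fixes.copy()
    for label in HABITAT_LABELS:
        out[label] = 0
    minx, miny, maxx, maxy = hmap.extent
    outside = ((fixes["x"] < minx) | (fixes["x"] > maxx)
               | (fixes["y"] < miny) | (fixes["y"] > maxy))
    if outside.any():
        warnings.warn(f"{int(outside.sum())} fixes outside map extent; "
                      "all habitat indicators set to 0", stacklevel=2)

    xs = fixes["x"].to_numpy()
    ys = fixes["y"].to_numpy()
    veg_hit = np.zeros(len(fixes), dtype=bool)
    lc_hit = np.zeros(len(fixes), dtype=bool)
    cols = {label: np.zeros(len(fixes), dtype=int) for label in HABITAT_LABELS}
    for label, poly in hmap.patches:
        taken = veg_hit if label in VEGETATION_LABELS else lc_hit
        inside = shapely.intersects_xy(poly, xs, ys) & ~taken
        cols[label][inside] = 1
        taken |= inside
    for label in HABITAT_LABELS:
        out[label] = cols[label]
    return out


def attach_temperature(fixes: pd.DataFrame, temps: pd.DataFrame) -> pd.DataFrame:
    """Join monthly average water temperature (column ``wt``) by survey round."""
    missing = sorted(set(fixes["survey_round"]) - set(temps["month"]))
    if missing:
        raise DataError(f"no temperature for survey month(s) {missing}")
    lut = dict(zip(temps["month"], temps["wt"]))
    out = fixes.copy()
    out["wt"] = fixes["survey_round"].map(lut).astype(float)
    return out


def lonlat_to_local(lon: np.ndarray, lat: np.ndarray,
                    origin: tuple[float, float] | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat (degrees) to local planar meters.

    Equirectangular about the data centroid (or a given ``origin``): an
    approximation, fine for sites up to ~10 km across.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if origin is None:
        origin = (float(lon.mean()), float(lat.mean()))
    lon0, lat0 = origin
    r_earth = 6_371_000.0
    x = np.deg2rad(lon - lon0) * r_earth * math.cos(math.radians(lat0))
    y = np.deg2rad(lat - lat0) * r_earth
    return x, y
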