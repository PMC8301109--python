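"""Per-step movement parameters: linear speed, bearing, turning angle,
angular speed, and their distribution summaries.

Bearings use the compass convention: north = 0 degrees, increasing
clockwise, in [0, 360). Turning angles are differences of consecutive
bearings wrapped into (-180, 180], with an exact reversal mapping to +180.
Linear speed (LiS) is displacement over elapsed time in m/h; angular speed
(AnS) is turning angle over the later step's elapsed time in degrees/h.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

STEP_COLUMNS = ["individual_id", "t0", "t1", "dt", "displacement",
                "linear_speed", "bearing", "turning_angle", "angular_speed"]


def bearing_deg(dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
    """Compass bearing of displacement vectors; NaN for zero displacement."""
    dx = np.asarray(dx, dtype=float)
    dy = np.asarray(dy, dtype=float)
    b = np.degrees(np.arctan2(dx, dy)) % 360.0
    return np.where((dx == 0) & (dy == 0), np.nan, b)


def wrap_turn(delta: np.ndarray) -> np.ndarray:
    """Wrap bearing differences into (-180, 180]; the boundary maps to +180."""
    wrapped = -((-np.asarray(delta, dtype=float) + 180.0) % 360.0 - 180.0)
    return wrapped


def compute_steps(fixes: pd.DataFrame, max_gap: float = 3.0) -> pd.DataFrame:
    """Per-step metrics for one individual's time-sorted fixes.

    Steps spanning more than ``max_gap`` hours (unobserved periods between
    survey nights) are dropped. The turning angle of a step is defined
    relative to the previous retained step only when the two are contiguous
    (they share a fix).

    Returns an empty table for fewer than two fixes. Raises ``ValueError``
    on non-positive time increments.
    """
    if fixes["individual_id"].nunique() > 1:
        raise ValueError("compute_steps expects fixes of a single individual")
    if len(fixes) < 2:
        return pd.DataFrame(columns=STEP_COLUMNS)

    t = pd.DatetimeIndex(fixes["timestamp"])
    dt_h = np.diff(t.view("int64")) / 3.6e12
    if np.any(dt_h <= 0):
        raise ValueError("non-positive time increment between consecutive fixes")
    x = fixes["x"].to_numpy(dtype=float)
    y = fixes["y"].to_numpy(dtype=float)
    dx = np.diff(x)
    dy = np.diff(y)
    disp = np.hypot(dx, dy)
    bear = bearing_deg(dx, dy)

    keep = dt_h <= max_gap
    # contiguous pairs of retained steps: step i follows step i-1 directly
    contiguous = np.zeros(len(dt_h), dtype=bool)
    contiguous[1:] = keep[1:] & keep[:-1]
    turn = np.full(len(dt_h), np.nan)
    prev_bear = np.concatenate([[np.nan], bear[:-1]])
    ok = contiguous & ~np.isnan(bear) & ~np.isnan(prev_bear)
    turn[ok] = wrap_turn(bear[ok] - prev_bear[ok])

    steps = pd.DataFrame({
        "individual_id": fixes["individual_id"].iloc[0],
        "t0": t[:-1],
        "t1": t[1:],
        "dt": dt_h,
        "displacement": disp,
        "linear_speed": disp / dt_h,
        "bearing": bear,
        "turning_angle": turn,
        "angular_speed": turn / dt_h,
    })
    return steps[keep].reset_index(drop=True)


def compute_steps_all(fixes: pd.DataFrame, max_gap: float = 3.0) -> pd.DataFrame:
    """`compute_steps` applied per individual, concatenated."""
    parts = [compute_steps(grp, max_gap=max_gap)
             for _, grp in fixes.groupby("individual_id", sort=True)
             if len(grp) >= 2]
    if not parts:
        return pd.DataFrame(columns=STEP_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def speed_histogram(steps: pd.DataFrame,
                    bins: np.ndarray | None = None) -> pd.DataFrame:
    """Histogram of linear speeds over log-spaced bins.

    Zero speeds land in a dedicated underflow bin (log bins cannot hold
    them); counts over all bins sum to the number of finite-speed steps.

    Returns a table with columns ``lo, hi, count``; the underflow row has
    ``lo = hi = 0``.
    """
    speeds = steps["linear_speed"].to_numpy(dtype=float)
    speeds = speeds[np.isfinite(speeds)]
    if np.any(speeds < 0):
        raise ValueError("negative speed")
    if bins is None:
        bins = np.logspace(0, np.log10(2000.0), 21)
    bins = np.asarray(bins, dtype=float)
    if np.any(np.diff(bins) <= 0):
        raise ValueError("bin edges must be strictly increasing")

    zero = speeds == 0
    counts, _ = np.histogram(speeds[~zero], bins=bins)
    # np.histogram drops values outside the range; park them in edge bins
    below = np.sum((speeds > 0) & (speeds < bins[0]))
    above = np.sum(speeds > bins[-1])
    counts = counts.astype(int)
    counts[0] += int(below)
    counts[-1] += int(above)
    rows = [{"lo": 0.0, "hi": 0.0, "count": int(zero.sum())}]
    rows += [{"lo": bins[i], "hi": bins[i + 1], "count": int(counts[i])}
             for i in range(len(counts))]
    return pd.DataFrame(rows)


def orientation_distribution(steps: pd.DataFrame,
                             n_sectors: int = 16) -> pd.DataFrame:
    """Counts of step bearings per angular sector partitioning [0, 360).

    Sector ``s`` covers ``[s*360/n, (s+1)*360/n)``. Steps with undefined
    bearing (zero displacement) are excluded.
    """
    if n_sectors < 2:
        raise ValueError("need at least 2 sectors")
    bear = steps["bearing"].to_numpy(dtype=float)
    bear = bear[~np.isnan(bear)]
    width = 360.0 / n_sectors
    idx = np.floor(bear / width).astype(int) % n_sectors
    counts = np.bincount(idx, minlength=n_sectors)
    return pd.DataFrame({
        "sector": np.arange(n_sectors),
        "lo": np.arange(n_sectors) * width,
        "hi": (np.arange(n_sectors) + 1) * width,
        "count": counts,
    })


def rayleigh_r(bearings_deg: np.ndarray) -> float:
    """Mean resultant length of a circular sample (0 = uniform, 1 = point mass)."""
    theta = np.deg2rad(np.asarray(bearings_deg, dtype=float))
    theta = theta[~np.isnan(theta)]
    if len(theta) == 0:
        return float("nan")
    return float(np.hypot(np.sin(theta).mean(), np.cos(theta).mean()))


def movement_summary(steps: pd.DataFrame) -> dict:
    """Headline moments of the step table: mean/SD linear speed, step count."""
    speeds = steps["linear_speed"].to_numpy(dtype=float)
    speeds = speeds[np.isfinite(speeds)]
    return {
        "n_steps": int(len(speeds)),
        "mean_speed": float(np.mean(speeds)) if len(speeds) else float("nan"),
        "sd_speed": float(np.std(speeds, ddof=1)) if len(speeds) > 1 else float("nan"),
        "resultant_length": rayleigh_r(steps["bearing"].to_numpy(dtype=float)),
    }
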