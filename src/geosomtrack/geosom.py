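"""Self-organizing map with a geographically constrained BMU search (Geo-SOM).

The map is a small 2-D lattice of nodes (reference 9x6), each holding a
weight vector over the named input variables. A designated subset of
variables (reference {X, Y}) is *geographic*. The best matching unit (BMU)
for a sample is found in two phases:

1. the *geo-winner* minimizes the summed squared distance restricted to the
   geographic variables;
2. the BMU minimizes the full summed squared distance among nodes within
   lattice distance ``k`` (the geographic tolerance) of the geo-winner.

``k = 0`` forces the geo-winner; ``k`` at or above the grid diameter
recovers the ordinary SOM. Weight updates use the bubble neighborhood:
every node within the current radius of the BMU moves by
``w' = w + eta * (x - w)``; all other nodes are untouched. Training runs
phases (reference: rough then fine) with radius and learning rate decaying
linearly within each phase; samples are presented in a seeded-shuffled
order once per pass.

Distances between weight and sample vectors are the summed *squared*
differences (no square root); the quantization error reported per pass is
the mean over samples of the square root of that distance at the BMU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class GeoTolerance:
    """Lattice radius of the constrained BMU search; k=0 pins the geo-winner."""
    k: int = 3

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("tolerance k must be >= 0")


@dataclass(frozen=True)
class TrainingPhase:
    """One training session: iteration count, initial radius and rate.

    Radius decays linearly to 1 (winner plus adjacent) and the rate to a
    tenth of its initial value across the iterations of the phase.
    """
    iterations: int
    initial_radius: float
    initial_rate: float

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.initial_radius < 0:
            raise ValueError("radius must be >= 0")
        if not 0 < self.initial_rate <= 1:
            raise ValueError("rate must be in (0, 1]")

    def schedule(self) -> list[tuple[float, float]]:
        """(radius, rate) per iteration, linear from initial to (1, rate/10)."""
        n = self.iterations
        if n == 1:
            return [(self.initial_radius, self.initial_rate)]
        radii = np.linspace(self.initial_radius, 1.0, n)
        rates = np.linspace(self.initial_rate, self.initial_rate / 10.0, n)
        return list(zip(radii, rates))


#: The printed reference schedule: rough 200 iterations (radius 4, rate 0.2)
#: then fine 20 iterations (radius 10, rate 0.1). The fine radius exceeding
#: the rough one is kept verbatim; see docs for a monotone alternative.
REFERENCE_PHASES = (TrainingPhase(200, 4.0, 0.2), TrainingPhase(20, 10.0, 0.1))
#: Monotone variant with a fine radius below the rough one.
MONOTONE_PHASES = (TrainingPhase(200, 4.0, 0.2), TrainingPhase(20, 2.0, 0.1))


@dataclass
class SomGrid:
    """Codebook of an (optionally geographic) SOM on a rectangular lattice.

    ``weights`` has shape (rows*cols, n_variables), row-major node order.
    Lattice distance is Chebyshev on (row, col) for the rectangular lattice
    and hex-grid steps for the hexagonal one.
    """
    rows: int
    cols: int
    variables: tuple[str, ...]
    geo_vars: tuple[str, ...] = ()
    lattice: str = "rectangular"
    weights: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.rows * self.cols < 4:
            raise ValueError("grid needs at least 4 nodes")
        if len(self.variables) == 0:
            raise ValueError("empty variable list")
        if self.lattice not in ("rectangular", "hexagonal"):
            raise ValueError(f"unknown lattice {self.lattice!r}")
        unknown = set(self.geo_vars) - set(self.variables)
        if unknown:
            raise ValueError(f"geo_vars not among variables: {sorted(unknown)}")
        if self.weights is None:
            self.weights = np.zeros((self.n_nodes, len(self.variables)))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.n_nodes, len(self.variables)):
            raise ValueError("weights shape mismatch")

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    @property
    def geo_idx(self) -> np.ndarray:
        return np.array([self.variables.index(v) for v in self.geo_vars],
                        dtype=int)

    def node_rc(self) -> np.ndarray:
        """(n_nodes, 2) array of (row, col) per node, row-major order."""
        r, c = np.divmod(np.arange(self.n_nodes), self.cols)
        return np.column_stack([r, c])

    def lattice_distances(self) -> np.ndarray:
        """(n_nodes, n_nodes) integer lattice distances between nodes."""
        rc = self.node_rc()
        if self.lattice == "rectangular":
            dr = np.abs(rc[:, None, 0] - rc[None, :, 0])
            dc = np.abs(rc[:, None, 1] - rc[None, :, 1])
            return np.maximum(dr, dc)
        # hexagonal: odd-r offset -> axial -> hex step distance
        q = rc[:, 1] - (rc[:, 0] - (rc[:, 0] & 1)) // 2
        r = rc[:, 0]
        dq = q[:, None] - q[None, :]
        dr = r[:, None] - r[None, :]
        return ((np.abs(dq) + np.abs(dr) + np.abs(dq + dr)) // 2).astype(int)

    def diameter(self) -> int:
        return int(self.lattice_distances().max())

    def copy(self) -> "SomGrid":
        return SomGrid(self.rows, self.cols, self.variables, self.geo_vars,
                       self.lattice, self.weights.copy())


def init_grid(rows: int, cols: int, variables, geo_vars=(),
              seed: int = 0, lattice: str = "rectangular") -> SomGrid:
    """Grid with weights drawn i.i.d. uniform on [0, 0.1] (small random start)."""
    if rows < 2 or cols < 2:
        raise ValueError("rows and cols must each be >= 2")
    variables = tuple(variables)
    rng = np.random.default_rng(seed)
    weights = rng.uniform(0.0, 0.1, size=(rows * cols, len(variables)))
    return SomGrid(rows, cols, variables, tuple(geo_vars), lattice, weights)


def node_distance(sample: np.ndarray, node_weights: np.ndarray) -> float:
    """Summed squared difference between a sample and one node's weights."""
    sample = np.asarray(sample, dtype=float)
    node_weights = np.asarray(node_weights, dtype=float)
    if sample.shape != node_weights.shape:
        raise ValueError("sample/weight length mismatch")
    diff = sample - node_weights
    return float(diff @ diff)


def _all_node_distances(grid: SomGrid, sample: np.ndarray,
                        idx: np.ndarray | None = None) -> np.ndarray:
    w = grid.weights if idx is None else grid.weights[:, idx]
    x = sample if idx is None else sample[idx]
    diff = w - x
    return np.einsum("nd,nd->n", diff, diff)


def find_bmu(sample: np.ndarray, grid: SomGrid,
             tolerance: GeoTolerance | None = None,
             lattice_d: np.ndarray | None = None) -> int:
    """Two-phase BMU search; ties broken by lowest node index.

    With no geographic variables or no tolerance given, this is the plain
    unconstrained argmin of the full distance.
    """
    sample = np.asarray(sample, dtype=float)
    if sample.shape != (len(grid.variables),):
        raise ValueError("sample length mismatch")
    full = _all_node_distances(grid, sample)
    if tolerance is None or len(grid.geo_vars) == 0:
        return int(np.argmin(full))
    geo = _all_node_distances(grid, sample, grid.geo_idx)
    gw = int(np.argmin(geo))
    if tolerance.k == 0:
        return gw
    if lattice_d is None:
        lattice_d = grid.lattice_distances()
    allowed = lattice_d[gw] <= tolerance.k
    constrained = np.where(allowed, full, np.inf)
    return int(np.argmin(constrained))


def update_weights(grid: SomGrid, bmu: int, sample: np.ndarray,
                   eta: float, radius: float,
                   lattice_d: np.ndarray | None = None) -> None:
    """Bubble update in place: nodes within ``radius`` of the BMU move
    toward the sample by fraction ``eta``; others are unchanged."""
    if not 0 <= eta <= 1:
        raise ValueError("eta must be in [0, 1]")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if lattice_d is None:
        lattice_d = grid.lattice_distances()
    mask = lattice_d[bmu] <= radius
    grid.weights[mask] += eta * (np.asarray(sample, dtype=float)
                                 - grid.weights[mask])


def _check_normalized(samples: np.ndarray, tol: float = 1e-9) -> None:
    if samples.size and (samples.min() < -tol or samples.max() > 1 + tol):
        raise ValueError(
            "training samples must be min-max normalized to [0, 1]; "
            f"found range [{samples.min():.3g}, {samples.max():.3g}]")


def _bmu_all(grid: SomGrid, samples: np.ndarray,
             tolerance: GeoTolerance | None,
             lattice_d: np.ndarray) -> np.ndarray:
    """Vectorized BMU per sample (used for diagnostics and mapping)."""
    full = cdist(samples, grid.weights, metric="sqeuclidean")
    if tolerance is None or len(grid.geo_vars) == 0:
        return np.argmin(full, axis=1)
    gi = grid.geo_idx
    geo = cdist(samples[:, gi], grid.weights[:, gi], metric="sqeuclidean")
    gw = np.argmin(geo, axis=1)
    if tolerance.k == 0:
        return gw
    allowed = lattice_d[gw] <= tolerance.k
    return np.argmin(np.where(allowed, full, np.inf), axis=1)


def quantization_error(grid: SomGrid, samples: np.ndarray,
                       tolerance: GeoTolerance | None = None) -> float:
    """Mean over samples of the root distance to their BMU's weights."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    lattice_d = grid.lattice_distances()
    bmus = _bmu_all(grid, samples, tolerance, lattice_d)
    diff = samples - grid.weights[bmus]
    return float(np.mean(np.sqrt(np.einsum("nd,nd->n", diff, diff))))


def train(grid: SomGrid, samples: np.ndarray,
          phases=REFERENCE_PHASES,
          tolerance: GeoTolerance | None = None,
          seed: int = 0) -> tuple[SomGrid, list[float]]:
    """Train a copy of the grid through the given phases.

    One iteration is one full pass over the samples in a seeded-shuffled
    order. Returns the trained grid and the quantization-error history (one
    entry before training, then one per iteration).
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] < 1:
        raise ValueError("need at least one sample")
    if samples.shape[1] != len(grid.variables):
        raise ValueError("sample width must match grid variables")
    _check_normalized(samples)

    out = grid.copy()
    lattice_d = out.lattice_distances()
    rng = np.random.default_rng(seed)
    qe_history = [quantization_error(out, samples, tolerance)]
    for phase in phases:
        for radius, rate in phase.schedule():
            order = rng.permutation(samples.shape[0])
            for s in samples[order]:
                bmu = find_bmu(s, out, tolerance, lattice_d)
                update_weights(out, bmu, s, rate, radius, lattice_d)
            qe_history.append(quantization_error(out, samples, tolerance))
    return out, qe_history


def map_samples(grid: SomGrid, samples: np.ndarray,
                tolerance: GeoTolerance | None = None) -> np.ndarray:
    """BMU node index per sample for a trained grid."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    return _bmu_all(grid, samples, tolerance, grid.lattice_distances())


def component_planes(grid: SomGrid) -> dict[str, np.ndarray]:
    """Per-variable node values min-max rescaled to [0, 1].

    A variable constant across nodes maps to 0.5 everywhere.
    """
    planes: dict[str, np.ndarray] = {}
    for j, var in enumerate(grid.variables):
        col = grid.weights[:, j]
        lo, hi = col.min(), col.max()
        if hi - lo == 0:
            planes[var] = np.full_like(col, 0.5)
        else:
            planes[var] = (col - lo) / (hi - lo)
    return planes


class MinMaxNormalizer:
    """Per-variable min-max scaling to [0, 1], invertible.

    Constant variables scale to 0 (and invert back to the constant).
    """

    def __init__(self) -> None:
        self.lo: np.ndarray | None = None
        self.hi: np.ndarray | None = None

    def fit(self, data: np.ndarray) -> "MinMaxNormalizer":
        data = np.atleast_2d(np.asarray(data, dtype=float))
        self.lo = np.nanmin(data, axis=0)
        self.hi = np.nanmax(data, axis=0)
        return self

    def transform(self, data: np.ndarray) -> np.ndarray:
        span = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
        return (np.asarray(data, dtype=float) - self.lo) / span

    def inverse(self, data: np.ndarray) -> np.ndarray:
        span = np.where(self.hi > self.lo, self.hi - self.lo, 1.0)
        return np.asarray(data, dtype=float) * span + self.lo


def save_model(path, grid: SomGrid, normalizer: MinMaxNormalizer | None = None,
               tolerance: GeoTolerance | None = None,
               meta: dict | None = None) -> None:
    """Serialize a trained map (and its normalizer) as JSON."""
    payload = {
        "rows": grid.rows, "cols": grid.cols,
        "variables": list(grid.variables),
        "geo_vars": list(grid.geo_vars),
        "lattice": grid.lattice,
        "weights": grid.weights.tolist(),
        "tolerance_k": None if tolerance is None else tolerance.k,
        "normalizer": None if normalizer is None else {
            "lo": normalizer.lo.tolist(), "hi": normalizer.hi.tolist()},
        "meta": meta or {},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path) -> tuple[SomGrid, MinMaxNormalizer | None,
                              GeoTolerance | None, dict]:
    with open(path) as fh:
        payload = json.load(fh)
    grid = SomGrid(payload["rows"], payload["cols"],
                   tuple(payload["variables"]), tuple(payload["geo_vars"]),
                   payload["lattice"], np.array(payload["weights"]))
    norm = None
    if payload["normalizer"] is not None:
        norm = MinMaxNormalizer()
        norm.lo = np.array(payload["normalizer"]["lo"])
        norm.hi = np.array(payload["normalizer"]["hi"])
    tol = (GeoTolerance(payload["tolerance_k"])
           if payload["tolerance_k"] is not None else None)
    return grid, norm, tol, payload["meta"]
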