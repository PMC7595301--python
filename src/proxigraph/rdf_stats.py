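"""Radial distribution statistics, exposure-time functionals and Monte Carlo baselines.

The radial distribution function g(r) measures the density of pairwise
distances at separation r, averaged over pairs and frames; its running integral
G(r) (the radial cumulative distribution function, RCDF) is normalized so that
rho * G(r) is the mean number of neighbors within distance r of a generic
pedestrian. In unconfined space G(r) = pi r^2; on a narrow platform the growth
crosses over from quadratic to linear near the platform width.

Estimators here come in three flavours sharing one container: a direct pairwise
histogram from trajectories, an edge-averaged estimate recovered from the
interaction graph (exactly equal in raw counts, by construction), and an
ensemble-averaged Monte Carlo baseline of hard-core uniformly random crowds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .interaction_graph import DistanceBinning, InteractionGraph
from .trajectory_io import PlatformGeometry, TrajectorySet, iter_frames

__all__ = [
    "RDFEstimate",
    "ExposureFunctional",
    "direct_rdf",
    "edge_average_rdf",
    "unconfined_rcdf",
    "mean_exposure_time",
    "t_of_r",
    "monte_carlo_rdf",
    "loglog_slope",
    "rdf_to_frame",
]

_MODES = ("raw", "total_n", "density")


@dataclass
class RDFEstimate:
    """Binned estimate of g(r)/G(r) with its normalization metadata.

    ``counts`` are raw (frame, unordered pair) event counts per bin, summed over
    all frames/realizations; they are the invariant representation from which
    every normalization mode is derived exactly:

    - ``raw``:      g_j = counts_j, G_j = prefix sum of counts.
    - ``total_n``:  g_j = c * counts_j / dr_j with c chosen so the integral of
                    g equals the mean occupancy N.
    - ``density``:  G(r) is the mean neighbor count within r divided by the
                    pair density rho, so G(r) -> pi r^2 for an unconfined
                    uniform crowd; g = dG/dr per bin.

    ``sum_occupancy`` is the total person-frame count (sum over frames of the
    number of pedestrians present), ``n_frames`` the number of frames or Monte
    Carlo realizations, ``rho`` the pair density in ped/m^2 when known.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    n_frames: int
    sum_occupancy: float
    rho: float | None = None
    empty: bool = False

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts and bin_edges are inconsistent")
        self.empty = bool(self.empty or self.counts.sum() == 0)

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def r_right(self) -> np.ndarray:
        return self.bin_edges[1:]

    @property
    def r_mid(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    @property
    def n_events(self) -> float:
        return float(self.counts.sum())

    @property
    def mean_occupancy(self) -> float:
        return self.sum_occupancy / self.n_frames if self.n_frames else 0.0

    def _require_rho(self) -> float:
        if self.rho is None or self.rho <= 0:
            raise ValueError("density normalization requires a positive pair density rho")
        return self.rho

    def g(self, mode: str = "raw") -> np.ndarray:
        if mode not in _MODES:
            raise ValueError(f"unknown normalization mode {mode!r}; choose from {_MODES}")
        if mode == "raw":
            return self.counts.copy()
        if mode == "total_n":
            total = self.counts.sum()
            if total == 0:
                return np.zeros_like(self.counts)
            c = self.mean_occupancy / total
            return c * self.counts / self.widths
        rho = self._require_rho()
        if self.sum_occupancy <= 0:
            return np.zeros_like(self.counts)
        return 2.0 * self.counts / (self.sum_occupancy * rho * self.widths)

    def G(self, mode: str = "raw") -> np.ndarray:
        """Cumulative distribution at the right bin edges; G(0) = 0 is implicit."""
        if mode == "raw":
            return np.cumsum(self.counts)
        return np.cumsum(self.g(mode) * self.widths)

    def G_at(self, r: float, mode: str = "density") -> float:
        """Linearly interpolated G(r); errors outside the binned support."""
        if r < 0 or r > self.bin_edges[-1]:
            raise ValueError(f"r = {r} outside binned support [0, {self.bin_edges[-1]}]")
        knots_r = np.concatenate(([self.bin_edges[0]], self.r_right))
        knots_G = np.concatenate(([0.0], self.G(mode)))
        return float(np.interp(r, knots_r, knots_G))


@dataclass(frozen=True)
class ExposureFunctional:
    """Average exposure-time functional: observation interval, density, critical distance.

    The mean exposure time of a pedestrian present for ``delta_t_s`` seconds in
    a crowd of density ``rho`` is T = delta_t * rho * G(r_c); its per-distance
    breakdown is t(r) = delta_t * rho * g(r).
    """

    delta_t_s: float
    rho: float
    r_c_m: float

    def __post_init__(self):
        if self.delta_t_s < 0 or self.rho < 0 or self.r_c_m < 0:
            raise ValueError("exposure functional parameters must be non-negative")


def _histogram_halfopen(d: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Histogram with half-open bins [e_j, e_{j+1}); values >= last edge dropped.

    The graph accumulator uses the same convention, so raw-count estimates from
    the two routes agree integer-exactly.
    """
    idx = np.searchsorted(edges, d, side="right") - 1
    keep = (idx >= 0) & (idx < len(edges) - 1) & (d < edges[-1])
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    np.add.at(counts, idx[keep], 1)
    return counts


def direct_rdf(
    ts: TrajectorySet,
    bin_width: float = 0.1,
    r_max: float | None = None,
    bin_edges=None,
    occupancy_band: tuple | None = None,
    geometry: PlatformGeometry | None = None,
    exclude_danger_zone: bool = False,
) -> RDFEstimate:
    """Histogram of all unordered pairwise distances over all frames.

    ``occupancy_band = (lo, hi)`` restricts to frames whose occupancy lies in
    the inclusive band (how measurements at comparable density levels are
    compared, e.g. 40-50 vs 70-80 passengers). With ``exclude_danger_zone``
    and a geometry, pairs whose midpoint lies in the danger zone are skipped.
    An empty frame selection yields an estimate flagged ``empty``.
    """
    if bin_edges is None:
        if not bin_width > 0:
            raise ValueError("bin_width must be positive")
        if r_max is None:
            r_max = (
                float(np.hypot(geometry.length_m, geometry.width_m))
                if geometry is not None
                else 5.0
            )
        edges = np.arange(0.0, r_max + bin_width, bin_width)
    else:
        edges = np.asarray(bin_edges, dtype=float)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)

    n_frames = 0
    sum_occ = 0.0
    for frame in iter_frames(ts):
        n = frame.occupancy
        if occupancy_band is not None and not (occupancy_band[0] <= n <= occupancy_band[1]):
            continue
        n_frames += 1
        sum_occ += n
        if n < 2:
            continue
        d = pdist(frame.xy)
        if exclude_danger_zone and geometry is not None:
            iu, ju = np.triu_indices(n, k=1)
            mids = (frame.xy[iu] + frame.xy[ju]) / 2.0
            d = d[~np.asarray(geometry.in_danger_zone(mids[:, 0], mids[:, 1]))]
        counts += _histogram_halfopen(d, edges)

    rho = None
    if geometry is not None and n_frames > 0 and sum_occ / n_frames > 1:
        rho = (sum_occ / n_frames - 1.0) / geometry.area_m2
    return RDFEstimate(
        bin_edges=edges,
        counts=counts,
        n_frames=n_frames,
        sum_occupancy=sum_occ,
        rho=rho,
        empty=n_frames == 0,
    )


def edge_average_rdf(graph: InteractionGraph, zone: str = "total", edge_mean: bool = False) -> RDFEstimate:
    """Recover the short-range RDF from the graph's edge weights (support r < D').

    With raw-count normalization (default), bin j equals the sum of the j-th
    edge-weight component over all edges — identical to the direct pairwise
    histogram coarse-binned at the graph's bin edges, because both count the
    same (frame, unordered pair) events. With ``edge_mean`` the per-bin value is
    instead the ensemble average over edges of w_j / sum_k w_k (each pair's
    normalized RDF contributing equally).
    """
    nb = graph.binning.n_bins
    if edge_mean:
        acc = np.zeros(nb, dtype=float)
        n = 0
        for rec in graph.edge_records():
            w = {"total": rec.w_total, "common": rec.w_common, "danger": rec.w_danger}[zone]
            tot = w.sum()
            if tot > 0:
                acc += w / tot
                n += 1
        counts = acc / n if n else acc
    else:
        counts = graph.total_bin_counts(zone=zone).astype(float)

    n_frames = max(len(graph.processed_frames), 1)
    sum_occ = float(sum(data["tau"] for _, data in graph.g.nodes(data=True)))
    rho = None
    if graph.geometry is not None and sum_occ / n_frames > 1:
        rho = (sum_occ / n_frames - 1.0) / graph.geometry.area_m2
    return RDFEstimate(
        bin_edges=np.asarray(graph.binning.edges_m),
        counts=counts,
        n_frames=n_frames,
        sum_occupancy=sum_occ,
        rho=rho,
        empty=graph.n_edges == 0,
    )


def unconfined_rcdf(rho: float, r) -> np.ndarray | float:
    """Expected neighbor count within r in unconfined space: pi r^2 rho."""
    if rho < 0:
        raise ValueError("density must be non-negative")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("r must be non-negative")
    out = np.pi * r**2 * rho
    return float(out) if out.ndim == 0 else out


def mean_exposure_time(e: ExposureFunctional, estimate: RDFEstimate) -> float:
    """Mean exposure time T = delta_t * rho * G(r_c), in seconds.

    ``estimate`` is interpreted under density normalization; ``r_c`` must lie
    within the binned support.
    """
    return e.delta_t_s * e.rho * estimate.G_at(e.r_c_m, mode="density")


def t_of_r(e: ExposureFunctional, estimate: RDFEstimate, r: float) -> float:
    """Exposure-time contribution per unit distance, t(r) = delta_t * rho * g(r)."""
    if r < estimate.bin_edges[0] or r >= estimate.bin_edges[-1]:
        raise ValueError(f"r = {r} outside binned support")
    j = int(np.searchsorted(estimate.bin_edges, r, side="right")) - 1
    return e.delta_t_s * e.rho * estimate.g(mode="density")[j]


def monte_carlo_rdf(
    n: int,
    geometry: PlatformGeometry,
    min_dist: float = 0.2,
    n_realizations: int = 200,
    seed=None,
    bin_width: float = 0.1,
    r_max: float | None = None,
) -> RDFEstimate:
    """Ensemble-averaged RDF of hard-core uniformly random crowds in the rectangle.

    Each realization places ``n`` points uniformly at random in the L x W
    rectangle subject to pairwise distances >= ``min_dist`` (the baseline crowd
    with no social structure). Counts are accumulated over realizations;
    normalization metadata is set so density-mode G(r) is directly comparable
    with pi r^2.
    """
    from .synthetic_crowd import generate_random_static

    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    rng = np.random.default_rng(seed)
    if r_max is None:
        r_max = float(np.hypot(geometry.length_m, geometry.width_m))
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    counts = np.zeros(len(edges) - 1, dtype=np.int64)
    for _ in range(n_realizations):
        pts = generate_random_static(n, geometry, min_dist=min_dist, seed=rng)
        if n >= 2:
            counts += _histogram_halfopen(pdist(pts), edges)
    rho = (n - 1) / geometry.area_m2 if n > 1 else None
    return RDFEstimate(
        bin_edges=edges,
        counts=counts,
        n_frames=n_realizations,
        sum_occupancy=float(n * n_realizations),
        rho=rho,
    )


def loglog_slope(estimate: RDFEstimate, r_lo: float, r_hi: float, mode: str = "density") -> float:
    """Least-squares slope of log G versus log r over right bin edges in [r_lo, r_hi].

    Quantifies the growth exponent of the RCDF (2 in the unconfined quadratic
    regime, 1 in the width-bound linear regime). Requires at least 3 bins with
    positive G in range.
    """
    if mode == "density" and estimate.rho is None:
        mode = "raw"  # slope is scale-invariant
    r = estimate.r_right
    G = estimate.G(mode)
    m = (r >= r_lo) & (r <= r_hi) & (G > 0)
    if m.sum() < 3:
        raise ValueError("need at least 3 bins with positive G in the requested range")
    slope, _ = np.polyfit(np.log(r[m]), np.log(G[m]), 1)
    return float(slope)


def rdf_to_frame(estimate: RDFEstimate, mode: str = "raw") -> pd.DataFrame:
    """Tabulate an estimate as (bin_lo, bin_hi, g, G) for export/plotting."""
    return pd.DataFrame(
        {
            "bin_lo": estimate.bin_edges[:-1],
            "bin_hi": estimate.bin_edges[1:],
            "g": estimate.g(mode),
            "G": estimate.G(mode),
        }
    )
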