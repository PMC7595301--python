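"""Streaming construction of the vector-weighted distance-interaction graph.

Every tracked pedestrian is a node carrying its persistence time (number of
frames observed), origin and latest position. Whenever two pedestrians are
observed in the same frame with Euclidean distance below the recording
threshold D' (2.5 m by default), the event is accumulated into a 5-bin distance
histogram on the edge joining them. Each edge carries two such count vectors:
one for events whose pair midpoint lies in the platform danger zone and one for
the rest; their elementwise sum is the total weight.

The structure is additive: it is built in a single forward pass over the frames
and is usable after any prefix of the stream, which makes it suitable for
real-time monitoring of large crowds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist

from .trajectory_io import Frame, PlatformGeometry, TrajectorySet, iter_frames

__all__ = [
    "DistanceBinning",
    "EdgeRecord",
    "InteractionGraph",
    "quantize",
    "build_graph",
    "window_split",
    "split_quiet_periods",
]

#: sentinel returned by :func:`quantize` for distances at or beyond D'
OUT_OF_RANGE = -1


@dataclass(frozen=True)
class DistanceBinning:
    """Radial quantization of pairwise distances.

    ``edges_m`` are the bin boundaries; bins are half-open ``[r_j, r_{j+1})``.
    ``physical_distance_m`` is the regulatory distance D (1.5 m in the
    Netherlands) and must coincide with one of the edges; the last edge is the
    recording threshold D' beyond which events are not stored.
    """

    edges_m: tuple = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5)
    physical_distance_m: float = 1.5

    def __post_init__(self):
        edges = np.asarray(self.edges_m, dtype=float)
        if edges[0] != 0.0:
            raise ValueError("first bin edge must be 0")
        if not np.all(np.diff(edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.physical_distance_m not in self.edges_m:
            raise ValueError("physical distance D must be one of the bin edges")
        if not self.physical_distance_m < edges[-1]:
            raise ValueError("physical distance D must be below the recording threshold D'")

    @property
    def recording_distance_m(self) -> float:
        """The recording threshold D' (last bin edge)."""
        return self.edges_m[-1]

    @property
    def n_bins(self) -> int:
        return len(self.edges_m) - 1

    @property
    def midpoints_m(self) -> np.ndarray:
        e = np.asarray(self.edges_m)
        return (e[:-1] + e[1:]) / 2.0

    @property
    def physical_bin_index(self) -> int:
        """Largest bin index whose right edge is at or below D."""
        return int(np.searchsorted(self.edges_m, self.physical_distance_m)) - 1


def quantize(d, binning: DistanceBinning | None = None):
    """Map a distance to its bin index, or :data:`OUT_OF_RANGE` for d >= D'.

    Bins are half-open, so a distance exactly on an interior edge falls in the
    higher bin (0.5 m -> bin 1) and d == D' is discarded. Negative distances
    raise ``ValueError``. Accepts scalars or arrays.
    """
    if binning is None:
        binning = DistanceBinning()
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("distances must be non-negative")
    edges = np.asarray(binning.edges_m)
    idx = np.searchsorted(edges, d_arr, side="right") - 1
    idx = np.where(d_arr >= binning.recording_distance_m, OUT_OF_RANGE, idx)
    if np.isscalar(d) or d_arr.ndim == 0:
        return int(idx)
    return idx.astype(int)


@dataclass(frozen=True)
class EdgeRecord:
    """Weights of one pedestrian pair: per-bin event counts split by zone."""

    u: str
    v: str
    w_common: np.ndarray
    w_danger: np.ndarray
    binning: DistanceBinning = field(default_factory=DistanceBinning)

    @property
    def w_total(self) -> np.ndarray:
        return self.w_common + self.w_danger


class InteractionGraph:
    """The distance-interaction graph H, backed by a :class:`networkx.Graph`.

    Node attributes: ``tau`` (persistence, frames), ``origin``, ``dest``.
    Edge attributes: ``w_common`` and ``w_danger``, integer count vectors of
    length ``binning.n_bins``. Edges are unordered pairs; there are no
    self-edges. ``processed_frames`` guards against double-counting a frame,
    which would break additivity.
    """

    def __init__(
        self,
        f: float,
        geometry: PlatformGeometry | None = None,
        binning: DistanceBinning | None = None,
    ):
        if not f > 0:
            raise ValueError("sampling frequency must be positive")
        self.f = float(f)
        self.geometry = geometry
        self.binning = binning if binning is not None else DistanceBinning()
        self.g = nx.Graph()
        self.processed_frames: set = set()

    # -- views ---------------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.g.number_of_edges()

    def nodes(self):
        return self.g.nodes

    def edges(self):
        return self.g.edges

    def tau(self, pid) -> int:
        return self.g.nodes[pid]["tau"]

    def tau_s(self, pid) -> float:
        return self.g.nodes[pid]["tau"] / self.f

    def edge_record(self, u, v) -> EdgeRecord:
        data = self.g.edges[u, v]
        return EdgeRecord(u=u, v=v, w_common=data["w_common"], w_danger=data["w_danger"], binning=self.binning)

    def edge_records(self) -> Iterable[EdgeRecord]:
        for u, v, data in self.g.edges(data=True):
            yield EdgeRecord(u=u, v=v, w_common=data["w_common"], w_danger=data["w_danger"], binning=self.binning)

    def neighbors(self, pid):
        return self.g.neighbors(pid)

    def total_bin_counts(self, zone: str = "total") -> np.ndarray:
        """Sum of edge weight vectors over the whole graph, by zone."""
        out = np.zeros(self.binning.n_bins, dtype=np.int64)
        for _, _, data in self.g.edges(data=True):
            if zone in ("total", "common"):
                out += data["w_common"]
            if zone in ("total", "danger"):
                out += data["w_danger"]
        return out

    # -- construction ----------------------------------------------------------

    def update(self, frame: Frame) -> "InteractionGraph":
        """Fold one frame into the graph (in place, additive).

        New pedestrians are added with origin set to their current position;
        persistence and destination are updated for every pedestrian present.
        Every unordered pair with distance < D' contributes exactly one count
        to the bin of its quantized distance, attributed to the danger-zone
        vector when the pair midpoint lies strictly inside the danger zone.
        """
        if frame.index in self.processed_frames:
            raise ValueError(f"frame {frame.index} already processed; re-processing would break additivity")
        self.processed_frames.add(frame.index)

        nb = self.binning.n_bins
        for pid, pos in zip(frame.ids, frame.xy):
            pos_t = (float(pos[0]), float(pos[1]))
            if pid in self.g:
                rec = self.g.nodes[pid]
                rec["tau"] += 1
                rec["dest"] = pos_t
            else:
                self.g.add_node(pid, tau=1, origin=pos_t, dest=pos_t)

        n = len(frame.ids)
        if n < 2:
            return self
        d = pdist(frame.xy)
        close = np.flatnonzero(d < self.binning.recording_distance_m)
        if close.size == 0:
            return self
        bins = quantize(d[close], self.binning)
        # recover (i, j) from condensed pdist indices
        iu, ju = np.triu_indices(n, k=1)
        ii, jj = iu[close], ju[close]
        mids = (frame.xy[ii] + frame.xy[jj]) / 2.0
        if self.geometry is not None:
            in_dz = np.asarray(self.geometry.in_danger_zone(mids[:, 0], mids[:, 1]))
        else:
            in_dz = np.zeros(len(close), dtype=bool)
        for k in range(len(close)):
            u, v = frame.ids[ii[k]], frame.ids[jj[k]]
            if u == v:  # defensive; duplicate ids are rejected upstream
                continue
            if not self.g.has_edge(u, v):
                self.g.add_edge(
                    u, v,
                    w_common=np.zeros(nb, dtype=np.int64),
                    w_danger=np.zeros(nb, dtype=np.int64),
                )
            key = "w_danger" if in_dz[k] else "w_common"
            self.g.edges[u, v][key][bins[k]] += 1
        return self

    def copy(self) -> "InteractionGraph":
        out = InteractionGraph(f=self.f, geometry=self.geometry, binning=self.binning)
        out.g = nx.Graph()
        for pid, data in self.g.nodes(data=True):
            out.g.add_node(pid, **dict(data))
        for u, v, data in self.g.edges(data=True):
            out.g.add_edge(u, v, w_common=data["w_common"].copy(), w_danger=data["w_danger"].copy())
        out.processed_frames = set(self.processed_frames)
        return out

    # -- comparison ------------------------------------------------------------

    def structurally_equal(self, other: "InteractionGraph") -> bool:
        """Node-, edge- and metadata-level equality (weights compared exactly)."""
        if not isinstance(other, InteractionGraph):
            return False
        if (
            self.f != other.f
            or self.binning != other.binning
            or self.geometry != other.geometry
            or self.processed_frames != other.processed_frames
        ):
            return False
        if set(self.g.nodes) != set(other.g.nodes):
            return False
        for pid in self.g.nodes:
            a, b = self.g.nodes[pid], other.g.nodes[pid]
            if a["tau"] != b["tau"] or a["origin"] != b["origin"] or a["dest"] != b["dest"]:
                return False
        if set(map(frozenset, self.g.edges)) != set(map(frozenset, other.g.edges)):
            return False
        for u, v, data in self.g.edges(data=True):
            o = other.g.edges[u, v]
            if not (
                np.array_equal(data["w_common"], o["w_common"])
                and np.array_equal(data["w_danger"], o["w_danger"])
            ):
                return False
        return True

    def __eq__(self, other):
        if not isinstance(other, InteractionGraph):
            return NotImplemented
        return self.structurally_equal(other)


def build_graph(
    ts: TrajectorySet,
    geometry: PlatformGeometry | None = None,
    binning: DistanceBinning | None = None,
) -> InteractionGraph:
    """Build the interaction graph in a single streaming pass over the frames.

    Equivalent by construction to folding :meth:`InteractionGraph.update` over
    ``iter_frames(ts)``; the graph is valid at any prefix of the stream.
    """
    graph = InteractionGraph(f=ts.f, geometry=geometry, binning=binning)
    for frame in iter_frames(ts):
        graph.update(frame)
    return graph


def split_quiet_periods(
    ts: TrajectorySet,
    occupancy_threshold: int = 2,
    quiet_duration_s: float = 120.0,
) -> list:
    """Cut the stream into segments separated by sustained low occupancy.

    A quiet period is a maximal run of frame indices (including indices with no
    stored frame, i.e. an empty platform) whose occupancy stays at or below
    ``occupancy_threshold`` for at least ``quiet_duration_s``. The stream is cut
    at the end of each qualifying quiet period; quiet frames attach to the
    preceding segment, so concatenating the segments reconstitutes the input.
    """
    if not quiet_duration_s > 0:
        raise ValueError("quiet_duration_s must be positive")
    if ts.n_frames == 0:
        return []
    idx = ts.frame_indices
    lo, hi = idx[0], idx[-1]
    quiet_frames_needed = int(np.ceil(quiet_duration_s * ts.f))

    occ = np.zeros(hi - lo + 1, dtype=int)
    for i, fr in ts.frames.items():
        occ[i - lo] = fr.occupancy
    quiet = occ <= occupancy_threshold

    cuts = []  # absolute frame index at which a new segment starts
    run_start = None
    for k in range(len(quiet)):
        if quiet[k]:
            if run_start is None:
                run_start = k
        else:
            if run_start is not None and k - run_start >= quiet_frames_needed:
                cuts.append(k + lo)
            run_start = None

    segments, current, b = [], {}, 0
    for i, fr in ts.frames.items():
        while b < len(cuts) and i >= cuts[b]:
            if current:
                segments.append(TrajectorySet(frames=current, f=ts.f))
                current = {}
            b += 1
        current[i] = fr
    if current:
        segments.append(TrajectorySet(frames=current, f=ts.f))
    return segments


def window_split(
    ts: TrajectorySet,
    geometry: PlatformGeometry | None = None,
    binning: DistanceBinning | None = None,
    occupancy_threshold: int = 2,
    quiet_duration_s: float = 120.0,
) -> list:
    """Build one interaction graph per low-occupancy-separated segment.

    Mirrors the operational practice of starting a fresh graph a couple of
    minutes after each train departure, when the platform is almost empty.
    Windowing is an efficiency device, not required for correctness.
    """
    segments = split_quiet_periods(ts, occupancy_threshold, quiet_duration_s)
    return [build_graph(seg, geometry=geometry, binning=binning) for seg in segments]
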