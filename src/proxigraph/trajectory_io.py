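"""Reading, validating and writing pedestrian trajectory data and serialized graphs.

Trajectories are time-stamped planar positions of identified pedestrians sampled
at a fixed frequency ``f`` (frames per second) by an overhead tracking system.
The interchange format is a UTF-8 CSV with header ``frame,id,x,y``: integer
frame index, opaque pedestrian id, coordinates in metres in a Cartesian frame
with origin at a platform corner and ``x`` along the platform length.

Tracks may have gaps (real sensors lose pedestrians); no interpolation is ever
performed. Graphs are serialized to a versioned JSON schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, Iterator, Union

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryPoint",
    "Frame",
    "TrajectorySet",
    "PlatformGeometry",
    "TrajectoryValidationError",
    "read_trajectories",
    "write_trajectories",
    "iter_frames",
    "write_graph",
    "read_graph",
    "GRAPH_SCHEMA_VERSION",
]

GRAPH_SCHEMA_VERSION = 1

PathOrFile = Union[str, "os.PathLike[str]", IO[str]]  # noqa: F821


class TrajectoryValidationError(ValueError):
    """Raised when trajectory input violates the format contract."""


@dataclass(frozen=True)
class TrajectoryPoint:
    """A single observation: pedestrian ``ped_id`` at ``(x, y)`` in frame ``frame``."""

    ped_id: str
    frame: int
    x: float
    y: float


@dataclass(frozen=True)
class Frame:
    """All pedestrians observed simultaneously in one frame.

    ``ids`` and ``xy`` are aligned: ``xy[i]`` is the position of ``ids[i]``.
    No pedestrian id may appear twice within a frame.
    """

    index: int
    ids: tuple
    xy: np.ndarray  # shape (n, 2), metres

    @property
    def occupancy(self) -> int:
        return len(self.ids)


@dataclass
class TrajectorySet:
    """Frame-ordered positions of identified pedestrians plus the sampling frequency."""

    frames: dict  # frame index -> Frame, kept sorted by key
    f: float  # frames per second

    def __post_init__(self):
        if not self.f > 0:
            raise TrajectoryValidationError(f"sampling frequency must be positive, got {self.f}")
        self.frames = dict(sorted(self.frames.items()))

    @property
    def frame_indices(self) -> list:
        return list(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def ped_ids(self) -> set:
        out = set()
        for fr in self.frames.values():
            out.update(fr.ids)
        return out

    def occupancy_series(self) -> pd.Series:
        """Number of pedestrians present per stored frame index."""
        return pd.Series({i: fr.occupancy for i, fr in self.frames.items()}, dtype=int)

    def duration_s(self) -> float:
        """Wall-clock span covered by the stored frames, in seconds."""
        if not self.frames:
            return 0.0
        idx = self.frame_indices
        return (idx[-1] - idx[0] + 1) / self.f

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, fr in self.frames.items():
            for pid, (x, y) in zip(fr.ids, fr.xy):
                rows.append((i, pid, x, y))
        return pd.DataFrame(rows, columns=["frame", "id", "x", "y"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, f: float) -> "TrajectorySet":
        return _build_set(df, f)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrajectorySet):
            return NotImplemented
        if self.f != other.f or self.frame_indices != other.frame_indices:
            return False
        for i in self.frames:
            a, b = self.frames[i], other.frames[i]
            if a.ids != b.ids or not np.array_equal(a.xy, b.xy):
                return False
        return True


@dataclass(frozen=True)
class PlatformGeometry:
    """Rectangular platform of ``length_m`` x ``width_m`` with a danger-zone strip.

    The danger zone is the strip of width ``danger_zone_m`` along the track-side
    long edge (largest ``y``), the buffer stepped on just before boarding.
    ``total_area_m2`` optionally overrides the rectangle area when the sensor
    coverage extends beyond the rectangle (e.g. under escalators); the usable
    area is always total area minus the danger-zone area.
    """

    length_m: float = 120.0
    width_m: float = 3.0
    danger_zone_m: float = 0.8
    total_area_m2: float | None = None

    def __post_init__(self):
        if not (0 < self.danger_zone_m < self.width_m):
            raise ValueError(
                f"danger-zone width must lie in (0, width): got {self.danger_zone_m} "
                f"for width {self.width_m}"
            )

    @property
    def area_m2(self) -> float:
        return self.length_m * self.width_m

    @property
    def danger_area_m2(self) -> float:
        return self.length_m * self.danger_zone_m

    @property
    def usable_area_m2(self) -> float:
        total = self.total_area_m2 if self.total_area_m2 is not None else self.area_m2
        return total - self.danger_area_m2

    def in_danger_zone(self, x, y) -> np.ndarray | bool:
        """True where a point lies strictly inside the danger-zone strip.

        Points exactly on the inner boundary count as common zone.
        """
        return np.asarray(y) > self.width_m - self.danger_zone_m

    def contains(self, x, y) -> np.ndarray | bool:
        x, y = np.asarray(x), np.asarray(y)
        return (x >= 0) & (x <= self.length_m) & (y >= 0) & (y <= self.width_m)

    def to_dict(self) -> dict:
        return {
            "length_m": self.length_m,
            "width_m": self.width_m,
            "danger_zone_m": self.danger_zone_m,
            "total_area_m2": self.total_area_m2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlatformGeometry":
        return cls(**d)


def _build_set(df: pd.DataFrame, f: float) -> TrajectorySet:
    required = ["frame", "id", "x", "y"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrajectoryValidationError(f"missing required column(s) {missing}; header must be frame,id,x,y")

    frame_col = pd.to_numeric(df["frame"], errors="coerce")
    if frame_col.isna().any():
        row = int(df.index[frame_col.isna()][0])
        raise TrajectoryValidationError(f"non-numeric frame index at row {row}")
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals)
        if bad.any():
            row = int(df.index[bad][0])
            raise TrajectoryValidationError(f"non-numeric or non-finite coordinate '{col}' at row {row}")
    if (frame_col < 0).any():
        row = int(df.index[frame_col < 0][0])
        raise TrajectoryValidationError(f"negative frame index at row {row}")

    clean = pd.DataFrame(
        {
            "frame": frame_col.astype(int),
            "id": df["id"].astype(str),
            # str -> float via astype: correctly rounded, so text round trips exactly
            "x": df["x"].astype(float),
            "y": df["y"].astype(float),
        },
        index=df.index,
    )
    dup = clean.duplicated(subset=["frame", "id"], keep="first")
    if dup.any():
        row = int(clean.index[dup][0])
        rec = clean.loc[row]
        raise TrajectoryValidationError(
            f"duplicate (id, frame) pair at row {row}: id={rec['id']!r}, frame={int(rec['frame'])}"
        )

    frames = {}
    # canonical within-frame order (by id) so logically equal inputs compare equal
    for idx, grp in clean.sort_values(["frame", "id"]).groupby("frame", sort=True):
        frames[int(idx)] = Frame(
            index=int(idx),
            ids=tuple(grp["id"]),
            xy=np.ascontiguousarray(grp[["x", "y"]].to_numpy(dtype=float)),
        )
    return TrajectorySet(frames=frames, f=f)


def read_trajectories(source: PathOrFile, f: float) -> TrajectorySet:
    """Read a ``frame,id,x,y`` CSV into a :class:`TrajectorySet`.

    Rows may arrive in any order; frames are assembled and sorted. Gaps in a
    pedestrian's frame sequence are preserved. Duplicate ``(id, frame)`` pairs
    and non-numeric coordinates raise :class:`TrajectoryValidationError` naming
    the offending row (0-based, header excluded).
    """
    if not f > 0:
        raise TrajectoryValidationError(f"sampling frequency must be positive, got {f}")
    df = pd.read_csv(source, dtype=str, skipinitialspace=True)
    return _build_set(df, f)


def write_trajectories(ts: TrajectorySet, sink: PathOrFile) -> None:
    """Write a trajectory set in the CSV interchange dialect."""
    ts.to_dataframe().to_csv(sink, index=False)


def iter_frames(ts: TrajectorySet) -> Iterator[Frame]:
    """Yield frames in strictly increasing frame-index order, each exactly once."""
    yield from ts.frames.values()


# ---------------------------------------------------------------------------
# Graph serialization (JSON, versioned schema)
# ---------------------------------------------------------------------------


def _runs(sorted_ints: list) -> list:
    """Run-length encode a sorted integer list as [start, stop] inclusive pairs."""
    runs = []
    for v in sorted_ints:
        if runs and v == runs[-1][1] + 1:
            runs[-1][1] = v
        else:
            runs.append([v, v])
    return runs


def _unruns(runs: list) -> set:
    out = set()
    for a, b in runs:
        out.update(range(a, b + 1))
    return out


def write_graph(graph, sink: PathOrFile) -> None:
    """Serialize an interaction graph to versioned JSON."""
    payload = {
        "schema_version": GRAPH_SCHEMA_VERSION,
        "f_hz": graph.f,
        "binning": {
            "edges_m": list(graph.binning.edges_m),
            "physical_distance_m": graph.binning.physical_distance_m,
            "recording_distance_m": graph.binning.recording_distance_m,
        },
        "geometry": graph.geometry.to_dict() if graph.geometry is not None else None,
        "processed_frames": _runs(sorted(graph.processed_frames)),
        "nodes": [
            {
                "id": pid,
                "tau_frames": rec["tau"],
                "origin": list(rec["origin"]),
                "dest": list(rec["dest"]),
            }
            for pid, rec in sorted(graph.g.nodes(data=True))
        ],
        "edges": [
            {
                "u": u,
                "v": v,
                "w_common": [int(c) for c in data["w_common"]],
                "w_danger": [int(c) for c in data["w_danger"]],
            }
            for u, v, data in sorted(graph.g.edges(data=True))
        ],
    }
    if hasattr(sink, "write"):
        json.dump(payload, sink)
    else:
        with open(sink, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)


def read_graph(source: PathOrFile):
    """Load an interaction graph from JSON written by :func:`write_graph`.

    Raises ``ValueError`` on a schema-version mismatch.
    """
    from .interaction_graph import DistanceBinning, InteractionGraph

    if hasattr(source, "read"):
        payload = json.load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            payload = json.load(fh)

    version = payload.get("schema_version")
    if version != GRAPH_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported graph schema version {version!r}; this reader supports {GRAPH_SCHEMA_VERSION}"
        )

    b = payload["binning"]
    binning = DistanceBinning(
        edges_m=tuple(b["edges_m"]),
        physical_distance_m=b["physical_distance_m"],
    )
    geometry = PlatformGeometry.from_dict(payload["geometry"]) if payload["geometry"] else None
    graph = InteractionGraph(f=payload["f_hz"], geometry=geometry, binning=binning)
    graph.processed_frames.update(_unruns(payload["processed_frames"]))
    for node in payload["nodes"]:
        graph.g.add_node(
            node["id"],
            tau=int(node["tau_frames"]),
            origin=tuple(node["origin"]),
            dest=tuple(node["dest"]),
        )
    for edge in payload["edges"]:
        graph.g.add_edge(
            edge["u"],
            edge["v"],
            w_common=np.asarray(edge["w_common"], dtype=np.int64),
            w_danger=np.asarray(edge["w_danger"], dtype=np.int64),
        )
    return graph
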