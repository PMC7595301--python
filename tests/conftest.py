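"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's accumulation code paths: they
re-count (frame, unordered pair) events with plain Python double loops so that
graph-based statistics can be checked by exact integer equality.
"""

import itertools
import math

import numpy as np
import pytest

from proxigraph import (
    DistanceBinning,
    Frame,
    InteractionGraph,
    PlatformGeometry,
    ScenarioConfig,
    TrajectorySet,
    build_graph,
    generate_scenario,
)

EDGES = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5)


@pytest.fixture
def geometry():
    return PlatformGeometry()


@pytest.fixture
def binning():
    return DistanceBinning()


def make_frame(index, positions):
    """Frame from {ped_id: (x, y)}."""
    ids = tuple(positions)
    xy = np.array([positions[i] for i in ids], dtype=float)
    return Frame(index=index, ids=ids, xy=xy)


def make_ts(frames, f=10.0):
    return TrajectorySet(frames={fr.index: fr for fr in frames}, f=f)


def make_graph(taus, edges, f=10.0, geometry=None):
    """Interaction graph with prescribed node persistences and edge weights.

    ``taus``: {id: tau_frames}; ``edges``: {(u, v): w_total} or
    {(u, v): (w_common, w_danger)}.
    """
    g = InteractionGraph(f=f, geometry=geometry)
    for pid, tau in taus.items():
        g.g.add_node(pid, tau=int(tau), origin=(0.0, 0.0), dest=(0.0, 0.0))
    for (u, v), w in edges.items():
        w = np.asarray(w, dtype=np.int64)
        if w.ndim == 2:
            wc, wd = w
        else:
            wc, wd = w, np.zeros_like(w)
        g.g.add_edge(u, v, w_common=wc, w_danger=wd)
    return g


def brute_force_bin_counts(ts, geometry, edges=EDGES):
    """Per-bin (common, danger) event counts by per-frame pair enumeration."""
    nb = len(edges) - 1
    common, danger = [0] * nb, [0] * nb
    boundary = geometry.width_m - geometry.danger_zone_m
    for fr in ts.frames.values():
        pts = list(zip(fr.ids, fr.xy))
        for (_, pa), (_, pb) in itertools.combinations(pts, 2):
            d = math.hypot(pa[0] - pb[0], pa[1] - pb[1])
            if d >= edges[-1]:
                continue
            j = max(k for k in range(nb) if edges[k] <= d)
            if (pa[1] + pb[1]) / 2.0 > boundary:
                danger[j] += 1
            else:
                common[j] += 1
    return np.array(common), np.array(danger)


def brute_force_edge_weights(ts, geometry, edges=EDGES):
    """Per-pair total weight vectors, keyed by frozenset pair."""
    nb = len(edges) - 1
    weights = {}
    for fr in ts.frames.values():
        pts = list(zip(fr.ids, fr.xy))
        for (ia, pa), (ib, pb) in itertools.combinations(pts, 2):
            d = math.hypot(pa[0] - pb[0], pa[1] - pb[1])
            if d >= edges[-1]:
                continue
            j = max(k for k in range(nb) if edges[k] <= d)
            weights.setdefault(frozenset((ia, ib)), np.zeros(nb, dtype=int))[j] += 1
    return weights


def brute_force_exposure(ts, pid, r_max):
    """Seconds of co-presence of ``pid`` with anyone strictly within r_max."""
    frames_in_contact = 0
    for fr in ts.frames.values():
        if pid not in fr.ids:
            continue
        i = fr.ids.index(pid)
        for j in range(fr.occupancy):
            if j == i:
                continue
            d = math.hypot(*(fr.xy[i] - fr.xy[j]))
            if d < r_max:
                frames_in_contact += 1
    return frames_in_contact / ts.f


def random_walk_ts(n_peds=20, n_frames=30, box=(10.0, 3.0), step=0.3, seed=0, f=10.0):
    """Dense random-walk trajectories producing many sub-D' events."""
    rng = np.random.default_rng(seed)
    pos = rng.random((n_peds, 2)) * box
    frames = {}
    for t in range(n_frames):
        pos = np.clip(pos + rng.normal(0, step, pos.shape), 0, box)
        frames[t] = Frame(index=t, ids=tuple(f"p{i}" for i in range(n_peds)), xy=pos.copy())
    return TrajectorySet(frames=frames, f=f)


def wanderer_config(seed=0, n_singles=14, family_sizes=(), wanderer_targets=12):
    """Clean fixture for offender detection: wide lane-to-band clearance."""
    return ScenarioConfig(
        seed=seed,
        n_singles=n_singles,
        family_sizes=family_sizes,
        n_wanderers=1,
        min_stranger_sep_m=3.0,
        waiting_band_m=(2.05, 2.15),
        lane_y_m=0.25,
        duration_s=180.0,
        train_times_s=(170.0,),
        entry_window_s=(2.0, 15.0),
        wanderer_targets=wanderer_targets,
    )


def large_scenario_config(seed=0):
    """200 pedestrians over ~2000 frames, spread over six train events."""
    return ScenarioConfig(
        seed=seed,
        duration_s=199.9,
        n_singles=140,
        family_sizes=(2,) * 18 + (3,) * 8,
        train_times_s=(30.0, 64.0, 98.0, 132.0, 166.0, 199.0),
        entry_window_s=(2.0, 12.0),
    )


@pytest.fixture(scope="session")
def large_scenario():
    cfg = large_scenario_config(seed=42)
    ts, gt = generate_scenario(cfg)
    graph = build_graph(ts, geometry=cfg.geometry)
    return cfg, ts, gt, graph
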