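"""Seeded generator of platform crowd scenarios with planted ground truth.

Emulates a train-platform crowd: pedestrians enter around train events, walk to
a waiting spot, dwell, and board through the danger zone. Family-groups share a
moving anchor with fixed individual offsets, so their mutual proximity is
time-consistent by construction (the signature the family detector is designed
to recover). Solitary passengers keep a minimum stranger separation while
waiting. Wanderers roam a walking lane and pause briefly near many distinct
waiting passengers — planted contact-heavy offenders.

Motion is piecewise-linear between waypoints at constant speed with independent
per-frame positional jitter mimicking sensor noise; no behavioural realism
(collision avoidance, social forces) is attempted or needed for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .trajectory_io import PlatformGeometry, TrajectorySet

__all__ = [
    "ScenarioConfig",
    "ScenarioGroundTruth",
    "generate_scenario",
    "generate_random_static",
    "ground_truth_to_frame",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Scenario parameters; defaults emulate a Dutch-platform validation crowd.

    ``family_sizes`` plants one group per entry (sizes in {2, 3, 4}); the
    default is ten pairs and two triples among fifty solitary passengers.
    ``train_times_s`` are boarding events; units are spread round-robin over
    them and enter shortly after the previous departure. With
    ``entry_points=None`` each unit enters on the non-track edge directly below
    its waiting spot (perpendicular walk-in corridors that do not sweep past
    other units); explicit shared entry points may be supplied instead.
    ``min_stranger_sep_m`` is the hard-core separation between waiting
    spots (group blobs get extra padding of their radius), chosen above the
    regulation distance so planted strangers stay compliant while waiting.
    """

    geometry: PlatformGeometry = field(default_factory=PlatformGeometry)
    f: float = 10.0
    duration_s: float = 150.0
    n_singles: int = 50
    family_sizes: tuple = (2, 2, 2, 2, 2, 2, 2, 2, 2, 2, 3, 3)
    n_wanderers: int = 0
    intra_group_mean_m: float = 0.45
    intra_group_spread_m: float = 0.05
    min_stranger_sep_m: float = 2.0
    waiting_band_m: tuple = (1.15, 2.15)
    lane_y_m: float = 0.3
    approach_dist_m: float = 0.7
    train_times_s: tuple | None = None
    entry_points: tuple | None = None
    entry_window_s: tuple = (2.0, 20.0)
    wanderer_targets: int = 12
    wanderer_pause_s: float = 2.0
    speed_range_mps: tuple = (1.0, 1.5)
    jitter_std_m: float = 0.05
    x_margin_m: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_singles < 0 or self.n_wanderers < 0:
            raise ValueError("counts must be non-negative")
        if any(k < 2 or k > 4 for k in self.family_sizes):
            raise ValueError("family sizes must lie in {2, 3, 4}")
        if not self.intra_group_mean_m < 1.0:
            raise ValueError("intra-group mean distance must stay below 1.0 m for planted families")
        if not self.f > 0 or not self.duration_s > 0:
            raise ValueError("f and duration must be positive")

    @property
    def trains(self) -> tuple:
        """Boarding events; by default two trains so the platform clears mid-run."""
        if self.train_times_s is not None:
            return tuple(sorted(self.train_times_s))
        return (0.45 * self.duration_s, self.duration_s - 20.0)


@dataclass
class ScenarioGroundTruth:
    """Planted memberships: pedestrian id -> group id and behavioural role."""

    group_of: dict  # id -> group id (singletons for singles/wanderers)
    role_of: dict  # id -> 'single' | 'family' | 'wanderer'

    def family_pairs(self) -> set:
        """All unordered within-group pairs of planted family members."""
        groups: dict = {}
        for pid, gid in self.group_of.items():
            if self.role_of[pid] == "family":
                groups.setdefault(gid, []).append(pid)
        pairs = set()
        for members in groups.values():
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    pairs.add(frozenset((members[i], members[j])))
        return pairs

    def family_groups(self) -> list:
        groups: dict = {}
        for pid, gid in self.group_of.items():
            if self.role_of[pid] == "family":
                groups.setdefault(gid, set()).add(pid)
        return sorted((frozenset(g) for g in groups.values()), key=lambda c: sorted(c))


def generate_random_static(n: int, geometry: PlatformGeometry, min_dist: float = 0.2, seed=None) -> np.ndarray:
    """One hard-core uniform placement of ``n`` points in the platform rectangle.

    Points are drawn uniformly, rejecting any candidate closer than
    ``min_dist`` to an accepted point, with a bounded retry budget and a full
    restart fallback. Raises ``RuntimeError`` when placement keeps failing
    (density too close to the packing limit).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n < 0:
        raise ValueError("n must be non-negative")
    L, W = geometry.length_m, geometry.width_m
    # loose feasibility bound: disks of diameter min_dist at hexagonal packing
    if min_dist > 0:
        capacity = 0.9069 * (L + min_dist) * (W + min_dist) / (np.pi * (min_dist / 2) ** 2)
        if n > capacity:
            raise ValueError(f"cannot place {n} points with min_dist={min_dist} in {L}x{W} m")
    return _hard_core(n, (0.0, L), (0.0, W), np.zeros(n) + min_dist / 2.0, rng)


def _hard_core(n, x_range, y_range, radii, rng, retries_per_point=10_000, restarts=5) -> np.ndarray:
    """Sequential rejection sampling with per-point radii (pairwise gap >= r_i + r_j)."""
    for _ in range(restarts):
        pts = np.empty((n, 2))
        ok = True
        for k in range(n):
            for _ in range(retries_per_point):
                cand = np.array(
                    [rng.uniform(*x_range), rng.uniform(*y_range)]
                )
                if k == 0:
                    pts[0] = cand
                    break
                gaps = np.hypot(pts[:k, 0] - cand[0], pts[:k, 1] - cand[1]) - (radii[:k] + radii[k])
                if gaps.min() >= 0:
                    pts[k] = cand
                    break
            else:
                ok = False
                break
        if ok:
            return pts
    raise RuntimeError(
        f"hard-core placement of {n} points failed after {restarts} restarts; "
        "lower n or the minimum separation"
    )


# ---------------------------------------------------------------------------
# Scenario assembly
# ---------------------------------------------------------------------------


@dataclass
class _Unit:
    """A single, family-group or wanderer travelling as one scheduling unit."""

    kind: str
    gid: str
    size: int
    cohort: int
    blob_radius: float
    spot: np.ndarray | None = None
    t_entry: float = 0.0
    t_arrive: float = 0.0
    waypoints: list | None = None  # [(t, x, y)]
    offsets: np.ndarray | None = None  # (size, 2)
    t_end: float = 0.0


def _blob_radius(k: int, intra_mean: float) -> float:
    if k <= 1:
        return 0.0
    if k == 2:
        return intra_mean / 2.0
    return intra_mean / (2.0 * np.sin(np.pi / k))


def _member_offsets(k: int, intra_mean: float, spread: float, rng) -> np.ndarray:
    if k == 1:
        return np.zeros((1, 2))
    radius = _blob_radius(k, intra_mean)
    phase = rng.uniform(0, 2 * np.pi)
    angles = phase + 2 * np.pi * np.arange(k) / k
    offs = radius * np.column_stack([np.cos(angles), np.sin(angles)])
    offs += rng.normal(0.0, spread / 2.0, size=(k, 2))
    return offs


def _piecewise_position(waypoints, t):
    ts = np.array([w[0] for w in waypoints])
    xs = np.array([w[1] for w in waypoints])
    ys = np.array([w[2] for w in waypoints])
    return np.interp(t, ts, xs), np.interp(t, ts, ys)


def generate_scenario(cfg: ScenarioConfig):
    """Generate a scenario: returns ``(TrajectorySet, ScenarioGroundTruth)``.

    Deterministic under a fixed config (all randomness flows from
    ``cfg.seed``). Raises on infeasible separation constraints.
    """
    rng = np.random.default_rng(cfg.seed)
    geom = cfg.geometry
    trains = cfg.trains
    dz_y = geom.width_m - geom.danger_zone_m

    # -- build units and assign cohorts (round-robin over trains) ------------
    units: list = []
    k = 0
    for i in range(cfg.n_singles):
        units.append(_Unit("single", f"s{i:03d}", 1, k % len(trains), 0.0))
        k += 1
    for i, size in enumerate(cfg.family_sizes):
        units.append(
            _Unit("family", f"f{i:03d}", int(size), k % len(trains), _blob_radius(size, cfg.intra_group_mean_m))
        )
        k += 1
    wanderers = [_Unit("wanderer", f"w{i:03d}", 1, i % len(trains), 0.0) for i in range(cfg.n_wanderers)]

    # -- waiting spots: per-cohort hard-core placement ------------------------
    y_lo, y_hi = cfg.waiting_band_m
    if not (0 < y_lo < y_hi <= dz_y):
        raise ValueError("waiting band must lie inside the platform, below the danger zone")
    for cohort in range(len(trains)):
        members = [u for u in units if u.cohort == cohort]
        if not members:
            continue
        radii = np.array([u.blob_radius + cfg.min_stranger_sep_m / 2.0 for u in members])
        pts = _hard_core(
            len(members),
            (cfg.x_margin_m, geom.length_m - cfg.x_margin_m),
            (y_lo, y_hi),
            radii,
            rng,
        )
        for u, p in zip(members, pts):
            u.spot = p

    # -- schedules -------------------------------------------------------------
    def entry_point(spot):
        if cfg.entry_points is None:
            return np.array([spot[0], 0.0])
        pts = np.asarray(cfg.entry_points, dtype=float)
        return pts[np.argmin(np.hypot(pts[:, 0] - spot[0], pts[:, 1] - spot[1]))]

    for u in units:
        t_train = trains[u.cohort]
        t_prev = trains[u.cohort - 1] if u.cohort > 0 else 0.0
        lo, hi = cfg.entry_window_s
        u.t_entry = min(t_prev + rng.uniform(lo, hi), max(t_train - 5.0, t_prev))
        e = entry_point(u.spot)
        v = rng.uniform(*cfg.speed_range_mps)
        walk = float(np.hypot(*(u.spot - e))) / v
        u.t_arrive = min(u.t_entry + walk, t_train)
        door = np.array([u.spot[0], geom.width_m - 0.1])
        t_door = t_train + float(np.hypot(*(door - u.spot))) / v
        u.t_end = min(t_door + 0.5, cfg.duration_s)
        u.waypoints = [
            (u.t_entry, e[0], e[1]),
            (u.t_arrive, u.spot[0], u.spot[1]),
            (t_train, u.spot[0], u.spot[1]),
            (t_door, door[0], door[1]),
            (t_door + 0.5, door[0], door[1]),
        ]
        u.offsets = _member_offsets(u.size, cfg.intra_group_mean_m, cfg.intra_group_spread_m, rng)

    # -- wanderers: visit distinct singles via the walking lane ----------------
    for w in wanderers:
        t_train = trains[w.cohort]
        cohort_singles = [u for u in units if u.cohort == w.cohort and u.kind == "single"]
        if len(cohort_singles) < cfg.wanderer_targets:
            raise ValueError(
                f"wanderer needs {cfg.wanderer_targets} single targets in its cohort, "
                f"only {len(cohort_singles)} available"
            )
        cohort_singles.sort(key=lambda u: u.spot[0])
        start = rng.integers(0, len(cohort_singles) - cfg.wanderer_targets + 1)
        targets = cohort_singles[start : start + cfg.wanderer_targets]
        v = rng.uniform(*cfg.speed_range_mps)
        lane = cfg.lane_y_m
        t = max(u.t_arrive for u in targets) + 1.0
        entry = np.array([targets[0].spot[0], 0.0])
        wps = [(t, entry[0], entry[1])]
        t += lane / v
        wps.append((t, entry[0], lane))
        x_cur = entry[0]
        for tgt in targets:
            x_t, y_t = tgt.spot
            y_stand = y_t - cfg.approach_dist_m
            t += abs(x_t - x_cur) / v
            wps.append((t, x_t, lane))
            t += (y_stand - lane) / v
            wps.append((t, x_t, y_stand))
            t += cfg.wanderer_pause_s
            wps.append((t, x_t, y_stand))
            t += (y_stand - lane) / v
            wps.append((t, x_t, lane))
            x_cur = x_t
        if t > min(t_train, cfg.duration_s):
            raise ValueError(
                "wanderer visit schedule does not fit before its train departs; "
                "use fewer targets, a longer dwell window or closer spots"
            )
        t += lane / v
        wps.append((t, x_cur, 0.0))
        w.t_entry = wps[0][0]
        w.t_end = min(t, cfg.duration_s)
        w.waypoints = wps
        w.offsets = np.zeros((1, 2))

    units.extend(wanderers)

    # -- sample frames -----------------------------------------------------------
    n_frames = int(round(cfg.duration_s * cfg.f)) + 1
    t_grid = np.arange(n_frames) / cfg.f
    records = {"frame": [], "id": [], "x": [], "y": []}
    group_of, role_of = {}, {}
    for u in units:
        present = (t_grid >= u.t_entry) & (t_grid <= u.t_end)
        idx = np.flatnonzero(present)
        if idx.size == 0:
            continue
        ax, ay = _piecewise_position(u.waypoints, t_grid[idx])
        for m in range(u.size):
            pid = u.gid if u.size == 1 else f"{u.gid}_{m}"
            group_of[pid] = u.gid
            role_of[pid] = u.kind if u.kind != "wanderer" else "wanderer"
            x = ax + u.offsets[m, 0] + rng.normal(0.0, cfg.jitter_std_m, idx.size)
            y = ay + u.offsets[m, 1] + rng.normal(0.0, cfg.jitter_std_m, idx.size)
            np.clip(x, 0.0, geom.length_m, out=x)
            np.clip(y, 0.0, geom.width_m, out=y)
            records["frame"].extend(idx.tolist())
            records["id"].extend([pid] * idx.size)
            records["x"].extend(x.tolist())
            records["y"].extend(y.tolist())

    df = pd.DataFrame(records)
    ts = TrajectorySet.from_dataframe(df, f=cfg.f) if len(df) else TrajectorySet(frames={}, f=cfg.f)
    return ts, ScenarioGroundTruth(group_of=group_of, role_of=role_of)


def ground_truth_to_frame(gt: ScenarioGroundTruth) -> pd.DataFrame:
    """Tabulate ground truth as (id, group_id, role) for text export."""
    rows = [{"id": pid, "group_id": gt.group_of[pid], "role": gt.role_of[pid]} for pid in sorted(gt.group_of)]
    return pd.DataFrame(rows, columns=["id", "group_id", "role"])
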