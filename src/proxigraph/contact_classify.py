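"""Contact statistics, family-group detection and distance-offender classification.

All quantities derive from the interaction graph alone. Pairwise contact time
up to distance bin d is the frame count below that bin scaled by 1/f; a
pedestrian's individual exposure is the sum of contact times over its graph
neighbors. Two pedestrians are in a family relation when their mutual proximity
is time-consistent over their persistence: within 1.0 m for more than a
fraction lambda1 (40%) and within 1.5 m for more than lambda2 (90%) of the
longer of the two persistence times. Family groups appear as cliques of that
relation; pruning family edges leaves the graph of sporadic infringements, on
which offenders (family-discounted exposure above alpha) and repeated offenders
(more than 10 distinct sub-regulation contacts) are identified.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .interaction_graph import EdgeRecord, InteractionGraph
from .trajectory_io import PlatformGeometry, TrajectorySet, iter_frames

__all__ = [
    "ClassificationParams",
    "ClassificationReport",
    "contact_time",
    "mean_distance",
    "distance_variance",
    "individual_exposure",
    "is_family",
    "family_pairs",
    "family_cliques",
    "prune_family",
    "offenders",
    "classify",
    "density_series",
    "stratified_report",
    "degree_distribution",
    "exposure_pdf",
    "report_to_frame",
]

LABELS = ("compliant", "family-member", "offender", "repeated-offender")


@dataclass(frozen=True)
class ClassificationParams:
    """Thresholds of the family relation and the offender rules.

    ``lambda1``/``lambda2`` are the minimal proximity-time fractions within
    1.0 m (bins 0-1) and 1.5 m (bins 0-2). ``alpha_s`` is the minimal
    family-discounted exposure (seconds) tagging an offender; common presets
    are 0, 10 and 30 s. ``repeated_degree_threshold`` is the number of
    distinct sub-D contacts above which an offender is "repeated".
    ``min_family_persistence_s`` guards the family relation against short or
    broken tracks, which would otherwise inflate apparent family-groups.
    """

    lambda1: float = 0.40
    lambda2: float = 0.90
    alpha_s: float = 0.0
    repeated_degree_threshold: int = 10
    min_family_persistence_s: float = 10.0

    def __post_init__(self):
        if not (0 <= self.lambda1 <= 1 and 0 <= self.lambda2 <= 1):
            raise ValueError("lambda thresholds must lie in [0, 1]")
        if self.alpha_s < 0:
            raise ValueError("alpha must be non-negative")


@dataclass
class ClassificationReport:
    """Per-node classification outcome.

    ``labels`` partition the nodes into compliant / family-member / offender /
    repeated-offender (family-member takes precedence when a clique member also
    has non-family exposure; the unfiltered offender set is kept in
    ``offender_set``). Exposures are in seconds at the reporting bin depth
    ``d``; ``degree`` counts distinct sub-D contacts in the family-pruned graph.
    """

    labels: dict
    cliques: list  # list of frozensets
    exposure_s: dict  # T_p^d, on the full graph
    exposure_nonfamily_s: dict  # T_{p,f}^d, on the pruned graph
    degree: dict
    offender_set: set  # P'_alpha, unfiltered
    d: int
    params: ClassificationParams

    def clique_of(self) -> dict:
        out = {}
        for k, clique in enumerate(self.cliques):
            for pid in clique:
                out.setdefault(pid, k)
        return out

    def counts(self) -> dict:
        c = {lbl: 0 for lbl in LABELS}
        for lbl in self.labels.values():
            c[lbl] += 1
        return c


# ---------------------------------------------------------------------------
# Edge-level statistics
# ---------------------------------------------------------------------------


def _zone_weights(e: EdgeRecord, zone: str) -> np.ndarray:
    try:
        return {"total": e.w_total, "common": e.w_common, "danger": e.w_danger}[zone]
    except KeyError:
        raise ValueError(f"unknown zone {zone!r}; choose total, common or danger") from None


def contact_time(e: EdgeRecord, d: int, f: float, zone: str = "total") -> float:
    """Cumulative contact time, in seconds, over distance bins 0..d.

    d = 2 restricts to r <= 1.5 m (the Dutch-regulation exposure); d = 4
    includes every recorded interaction (r < D').
    """
    if not 0 <= d < e.binning.n_bins:
        raise ValueError(f"bin depth d must lie in [0, {e.binning.n_bins - 1}]")
    return float(_zone_weights(e, zone)[: d + 1].sum()) / f


def _weighted_moments(e: EdgeRecord, d: int, zone: str):
    w = _zone_weights(e, zone)[: d + 1].astype(float)
    total = w.sum()
    if total == 0:
        raise ValueError("zero contact time: distance statistics are undefined for this pair")
    mids = e.binning.midpoints_m[: d + 1]
    mean = float((mids * w).sum() / total)
    mean_sq = float((mids**2 * w).sum() / total)
    return mean, mean_sq


def mean_distance(e: EdgeRecord, d: int, zone: str = "total") -> float:
    """Contact-time-weighted mean distance (bin midpoints), in metres."""
    return _weighted_moments(e, d, zone)[0]


def distance_variance(e: EdgeRecord, d: int, zone: str = "total") -> float:
    """Variance of the quantized distance, <r^2> - <r>^2, in m^2.

    Small variance means the pair kept an almost fixed mutual distance —
    the time-consistency signature of people walking together.
    """
    mean, mean_sq = _weighted_moments(e, d, zone)
    return max(mean_sq - mean**2, 0.0)


# ---------------------------------------------------------------------------
# Node-level exposure and the family relation
# ---------------------------------------------------------------------------


def individual_exposure(
    graph: InteractionGraph,
    p,
    d: int,
    discount_family: bool = False,
    params: ClassificationParams | None = None,
) -> float:
    """Total exposure of pedestrian ``p``: summed contact times over neighbors.

    With ``discount_family``, neighbors in family relation with ``p`` are
    excluded (exposure to non-family members only).
    """
    if p not in graph.g:
        raise KeyError(f"unknown pedestrian {p!r}")
    if discount_family and params is None:
        params = ClassificationParams()
    total = 0.0
    for q in graph.neighbors(p):
        if discount_family and is_family(graph, p, q, params):
            continue
        total += contact_time(graph.edge_record(p, q), d, graph.f)
    return total


def is_family(graph: InteractionGraph, u, v, params: ClassificationParams | None = None) -> bool:
    """Whether the symmetric family relation holds between u and v.

    Both proximity-time fractions — frames within 1.0 m over persistence, and
    frames within 1.5 m over persistence — must exceed their thresholds for the
    *longer*-observed pedestrian (the min of the two ratios is tested). Both
    endpoints must persist at least the eligibility minimum. Zone split is
    ignored: the family criterion makes no distinction between platform zones.
    """
    if params is None:
        params = ClassificationParams()
    if not graph.g.has_edge(u, v):
        return False
    min_tau = params.min_family_persistence_s * graph.f
    tau_u, tau_v = graph.tau(u), graph.tau(v)
    if tau_u < min_tau or tau_v < min_tau:
        return False
    w = graph.edge_record(u, v).w_total
    b = graph.binning
    d1 = int(np.searchsorted(b.edges_m, 1.0)) - 1  # bins with r <= 1.0 m
    d2 = b.physical_bin_index  # bins with r <= D
    t1 = float(w[: d1 + 1].sum())  # frame counts; f cancels in the ratios
    t2 = float(w[: d2 + 1].sum())
    tau_max = max(tau_u, tau_v)
    return (t1 / tau_max > params.lambda1) and (t2 / tau_max > params.lambda2)


def family_pairs(graph: InteractionGraph, params: ClassificationParams | None = None) -> set:
    """All unordered pairs in family relation, as frozensets."""
    if params is None:
        params = ClassificationParams()
    return {frozenset((u, v)) for u, v in graph.g.edges if is_family(graph, u, v, params)}


def family_cliques(
    graph: InteractionGraph,
    params: ClassificationParams | None = None,
    transitive_closure: bool = False,
) -> list:
    """Family-groups: maximal cliques of the family relation (size >= 2).

    The relation is not transitive; by default groups are maximal completely
    connected sub-graphs of it. With ``transitive_closure`` groups are instead
    the connected components of the relation (a chain a~b~c with a!~c merges).
    """
    pairs = family_pairs(graph, params)
    rel = nx.Graph()
    rel.add_edges_from(tuple(p) for p in pairs)
    if transitive_closure:
        groups = nx.connected_components(rel)
    else:
        groups = nx.find_cliques(rel)
    return sorted(
        (frozenset(g) for g in groups if len(g) >= 2),
        key=lambda c: sorted(c),
    )


def prune_family(graph: InteractionGraph, params: ClassificationParams | None = None) -> InteractionGraph:
    """The family-pruned sub-graph H': same nodes, family edges removed.

    Remaining edges indicate sporadic (not time-consistent) distance
    infringements.
    """
    out = graph.copy()
    for pair in family_pairs(graph, params):
        out.g.remove_edge(*tuple(pair))
    return out


# ---------------------------------------------------------------------------
# Offender classification
# ---------------------------------------------------------------------------


def _sub_d_degree(hprime: InteractionGraph, p) -> int:
    """Distinct contacts of p with at least one recorded event below D."""
    dmax = hprime.binning.physical_bin_index
    return sum(
        1
        for q in hprime.neighbors(p)
        if hprime.edge_record(p, q).w_total[: dmax + 1].sum() > 0
    )


def offenders(
    hprime: InteractionGraph,
    params: ClassificationParams | None = None,
    d: int = 2,
    cliques: list | None = None,
    full_graph: InteractionGraph | None = None,
) -> ClassificationReport:
    """Classify nodes of the family-pruned graph H'.

    The offender set P'_alpha collects nodes whose family-discounted exposure
    at bin depth ``d`` strictly exceeds ``alpha``; repeated offenders are its
    members with more than the threshold number of distinct sub-D contacts in
    H'. Members of the supplied family cliques are labeled family-member
    (precedence over the offender labels); everyone else is compliant.
    ``full_graph`` (H, pre-pruning) supplies the undiscounted exposures; when
    omitted they equal the discounted ones.
    """
    if params is None:
        params = ClassificationParams()
    cliques = list(cliques) if cliques is not None else []
    family_members = set().union(*cliques) if cliques else set()

    exposure_nf = {p: individual_exposure(hprime, p, d) for p in hprime.g.nodes}
    if full_graph is not None:
        exposure = {p: individual_exposure(full_graph, p, d) for p in hprime.g.nodes}
    else:
        exposure = dict(exposure_nf)
    degree = {p: _sub_d_degree(hprime, p) for p in hprime.g.nodes}
    offender_set = {p for p, t in exposure_nf.items() if t > params.alpha_s}

    labels = {}
    for p in hprime.g.nodes:
        if p in family_members:
            labels[p] = "family-member"
        elif p in offender_set and degree[p] > params.repeated_degree_threshold:
            labels[p] = "repeated-offender"
        elif p in offender_set:
            labels[p] = "offender"
        else:
            labels[p] = "compliant"

    return ClassificationReport(
        labels=labels,
        cliques=cliques,
        exposure_s=exposure,
        exposure_nonfamily_s=exposure_nf,
        degree=degree,
        offender_set=offender_set,
        d=d,
        params=params,
    )


def classify(
    graph: InteractionGraph,
    params: ClassificationParams | None = None,
    d: int = 2,
    transitive_closure: bool = False,
) -> ClassificationReport:
    """End-to-end classification of a full interaction graph H.

    Detects family cliques, prunes family edges and runs the offender rules on
    the residual graph of sporadic infringements.
    """
    if params is None:
        params = ClassificationParams()
    cliques = family_cliques(graph, params, transitive_closure=transitive_closure)
    hprime = prune_family(graph, params)
    return offenders(hprime, params, d=d, cliques=cliques, full_graph=graph)


# ---------------------------------------------------------------------------
# Density stratification and distribution reporting
# ---------------------------------------------------------------------------


def density_series(ts: TrajectorySet, geometry: PlatformGeometry) -> pd.Series:
    """Per-frame crowd density: occupancy divided by the usable area (ped/m^2).

    The usable area is the total sensor area discounted of the danger zone.
    """
    if not geometry.usable_area_m2 > 0:
        raise ValueError("usable area must be positive")
    occ = ts.occupancy_series()
    return occ / geometry.usable_area_m2


def stratified_report(
    ts: TrajectorySet,
    graph: InteractionGraph,
    geometry: PlatformGeometry,
    params: ClassificationParams | None = None,
    bands=((0.0, 0.1), (0.1, 0.2), (0.2, 0.3), (0.3, 0.4), (0.4, 0.5)),
    d: int = 2,
    alphas=(0.0, 10.0, 30.0),
) -> pd.DataFrame:
    """Per-density-band fractions of contacted / exposed / family / offender nodes.

    Each node is assigned the mean ambient density over the frames in which it
    was observed, then nodes are stratified into the supplied density bands
    (half-open ``[lo, hi)``). Reported per band: fraction of nodes with any
    recorded contact, fraction in a family-group, and fractions with
    family-discounted exposure exceeding each ``alpha``.
    """
    if params is None:
        params = ClassificationParams()
    dens = density_series(ts, geometry)
    sums: dict = {}
    nframes: dict = {}
    for frame in iter_frames(ts):
        rho_t = dens.loc[frame.index]
        for pid in frame.ids:
            sums[pid] = sums.get(pid, 0.0) + rho_t
            nframes[pid] = nframes.get(pid, 0) + 1
    ambient = {pid: sums[pid] / nframes[pid] for pid in sums}

    cliques = family_cliques(graph, params)
    family_members = set().union(*cliques) if cliques else set()
    hprime = prune_family(graph, params)
    exposure_nf = {p: individual_exposure(hprime, p, d) for p in hprime.g.nodes}
    has_contact = {p: graph.g.degree(p) > 0 for p in graph.g.nodes}

    rows = []
    for lo, hi in bands:
        members = [p for p, rho in ambient.items() if lo <= rho < hi and p in graph.g]
        n = len(members)
        row = {"band_lo": lo, "band_hi": hi, "n_nodes": n}
        if n:
            row["frac_any_contact"] = sum(has_contact[p] for p in members) / n
            row["frac_family"] = sum(p in family_members for p in members) / n
            for a in alphas:
                row[f"frac_offender_alpha_{a:g}s"] = sum(exposure_nf[p] > a for p in members) / n
        else:
            row["frac_any_contact"] = np.nan
            row["frac_family"] = np.nan
            for a in alphas:
                row[f"frac_offender_alpha_{a:g}s"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def degree_distribution(hprime: InteractionGraph) -> pd.Series:
    """Counts of nodes per sub-D contact degree (degree 0 = no infringement)."""
    degs = [_sub_d_degree(hprime, p) for p in hprime.g.nodes]
    return pd.Series(degs, dtype=int).value_counts().sort_index()


def exposure_pdf(report: ClassificationReport, n_bins: int = 20):
    """Log-binned probability density of positive family-discounted exposures.

    Returns ``(bin_edges, pdf)``; the heavy tail of random encounter dynamics
    shows up as an approximate power law on these axes.
    """
    vals = np.asarray([t for t in report.exposure_nonfamily_s.values() if t > 0], dtype=float)
    if vals.size == 0:
        return np.array([]), np.array([])
    lo, hi = vals.min(), vals.max()
    if lo == hi:
        hi = lo * (1 + 1e-9) + 1e-12
    edges = np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)
    edges[0] *= 1 - 1e-12  # guard the extremes against logspace round-off
    edges[-1] *= 1 + 1e-12
    counts, edges = np.histogram(vals, bins=edges)
    pdf = counts / (vals.size * np.diff(edges))
    return edges, pdf


def report_to_frame(report: ClassificationReport, graph: InteractionGraph) -> pd.DataFrame:
    """Tabulate a classification report for text export."""
    clique_of = report.clique_of()
    rows = []
    for pid in sorted(report.labels):
        rows.append(
            {
                "id": pid,
                "label": report.labels[pid],
                "tau_s": graph.tau_s(pid),
                "exposure_s": report.exposure_s[pid],
                "exposure_nonfamily_s": report.exposure_nonfamily_s[pid],
                "degree": report.degree[pid],
                "clique_id": clique_of.get(pid, -1),
            }
        )
    return pd.DataFrame(rows, columns=["id", "label", "tau_s", "exposure_s", "exposure_nonfamily_s", "degree", "clique_id"])
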