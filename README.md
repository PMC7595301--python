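# proxigraph

Physical-distancing analytics for tracked pedestrian crowds: a streaming
**distance-interaction graph**, radial distribution functions, exposure times,
automated family-group detection and distance-offender classification — built
for operators of monitored public spaces (train platforms, stations, plazas)
who receive anonymous trajectory data from overhead tracking sensors and need
to answer, in real time and without storing microscopic positions: *who
violated the distancing rule, with how many people, for how long — and who was
simply walking with their family?*

## The method

Input is a stream of frames: positions `(x, y)` of identified pedestrians
sampled at `f` frames/s. In a single forward pass the package accumulates a
vector-weighted graph `H`:

- **Nodes** are pedestrians, carrying persistence `τ` (frames observed),
  origin and latest position.
- **Edges** appear whenever two pedestrians are observed simultaneously at
  Euclidean distance `r < D′ = 2.5 m`, and carry a 5-bin histogram of these
  events over the edges `{0, 0.5, 1.0, 1.5, 2.0, 2.5}` m — a per-pair discrete
  radial distribution function. Each edge keeps two such count vectors,
  `w = w_common + w_danger`, split by whether the pair midpoint lies in the
  platform **danger zone** (the 80 cm boarding strip along the track edge).

Everything else is derived from `H`:

- **Contact time** `T_e^d = f⁻¹ Σ_{j≤d} w_j`: seconds a pair spent below the
  right edge of bin `d` (`d = 2` ⇒ `r ≤ 1.5 m`, the Dutch regulation distance
  `D`); per-pair mean distance and variance from the same weighted moments.
- **Individual exposure** `T_p^d = Σ_{q ∈ N(p)} T_{(p,q)}^d` over graph
  neighbors.
- **Family relation** `p₁ ∼ p₂` ⇔
  `min(T_e^{(1)}/τ_{p₁}, T_e^{(1)}/τ_{p₂}) > λ⁽¹⁾ = 40 %` and
  `min(T_e^{(2)}/τ_{p₁}, T_e^{(2)}/τ_{p₂}) > λ⁽²⁾ = 90 %`, with `T^{(1)}`
  the contact time within 1.0 m and `T^{(2)}` within 1.5 m: people who spend
  most of their stay within regulation distance of each other, and a large
  fraction of it inside each other's private space, are a family-group.
  Groups are the cliques of `∼` (the relation is deliberately not closed
  transitively).
- **Offenders**: prune family edges to get `H′`; the set
  `P′_α = {p : T_{p,f}^d > α}` collects pedestrians with more than `α`
  seconds of non-family exposure, and members with more than 10 distinct
  sub-`D` contacts are **repeated offenders**.
- **RDF / RCDF**: the global radial distribution function `g(r)` (density of
  pairwise distances) and its integral `G(r)` — with `ρ G(r)` the mean number
  of neighbors within `r` — are recovered exactly from the edge weights at the
  coarse bins, or estimated at fine resolution directly from trajectories.
  Mean exposure follows as `T = ΔT · ρ · G(r_c)`. A Monte Carlo baseline
  places crowds uniformly at random with a 0.2 m hard core in the same
  geometry: its RCDF grows `∼r²` below the platform half-width and `∼r¹`
  beyond, the reference against which measured crowds are compared.

A seeded synthetic-scenario generator plants family-groups (co-moving with a
shared anchor), compliant solitary passengers and contact-heavy wanderers with
ground truth, so the whole pipeline is testable without any sensor data.

## Worked example

```python
import numpy as np
from proxigraph import (
    ScenarioConfig, generate_scenario, build_graph, classify,
    edge_average_rdf, monte_carlo_rdf, loglog_slope, PlatformGeometry,
    ClassificationParams,
)

cfg = ScenarioConfig(seed=7)          # 50 singles, 10 family pairs, 2 triples
ts, truth = generate_scenario(cfg)
graph = build_graph(ts, geometry=cfg.geometry)
print(f"{len(ts.ped_ids())} pedestrians, {ts.n_frames} frames "
      f"-> {graph.n_nodes} nodes, {graph.n_edges} edges")

report = classify(graph, ClassificationParams(alpha_s=0.0), d=2)
print("labels:", report.counts())
print("cliques recovered:", len(report.cliques),
      "| planted:", len(truth.family_groups()))

est = edge_average_rdf(graph)
print("edge-weight histogram (counts per 0.5 m bin):", est.counts.astype(int).tolist())

mc = monte_carlo_rdf(75, PlatformGeometry(), min_dist=0.2,
                     n_realizations=200, seed=7, r_max=32.0)
print(f"RCDF growth exponents: {loglog_slope(mc, 0.5, 1.5):.2f} (r in [0.5, 1.5] m), "
      f"{loglog_slope(mc, 5, 30):.2f} (r in [5, 30] m)")
```

Output:

```
76 pedestrians, 1292 frames -> 76 nodes, 37 edges
labels: {'compliant': 50, 'family-member': 26, 'offender': 0, 'repeated-offender': 0}
cliques recovered: 12 | planted: 12
edge-weight histogram (counts per 0.5 m bin): [6609, 2339, 0, 221, 6966]
RCDF growth exponents: 1.97 (r in [0.5, 1.5] m), 0.95 (r in [5, 30] m)
```

All 12 planted family-groups are recovered as cliques and every solitary
passenger stays compliant. The edge-weight histogram reads as pair-seconds per
distance band scaled by `f`: the mass below 1.0 m is family proximity, the
mass at 2.0–2.5 m is waiting passengers near the recording threshold. The
Monte Carlo exponents show the quadratic→linear crossover imposed by the
3 m-wide platform.

There is also a CLI mirroring the library (`proxigraph simulate | build |
classify | rdf | mc | report`, each taking `--config`, `--seed`, `--out`); run
`proxigraph --help`.

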