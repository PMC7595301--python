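# Methods

## The interaction graph and its accumulation

The central data structure is an additive graph `H` over tracked pedestrians.
For every frame, all unordered pairs with Euclidean distance `d < D′` add one
count to the bin `q(d)` of the pair's edge weight, with half-open bins
`[r_j, r_{j+1})` over edges `{0, 0.5, 1.0, 1.5, 2.0, 2.5}` m. Distances exactly
equal to `D′` are discarded (strict inequality, a measure-zero event for
continuous positions); a distance exactly on an interior edge falls in the
higher bin. The same half-open histogram convention is used by the direct
pairwise RDF estimator, which is what makes the edge-averaged and direct
estimates **integer-identical** rather than merely close — both count the same
set of (frame, unordered pair) events.

The zone split attributes an event to the danger-zone vector when the pair
*midpoint* lies strictly inside the strip within 0.8 m of the track-side long
edge; a midpoint exactly on the boundary counts as common zone. Midpoint
attribution and the boundary tie-break are package conventions — any fixed rule
preserving `w = w_common + w_danger` would do.

Additivity is load-bearing: `update` refuses to process a frame index twice,
node persistence/destination and edge counts only ever grow, and the graph is
valid after any prefix of the stream. The optional windowing utility cuts the
stream wherever occupancy stays at or below a threshold (default 2 pedestrians)
for a sustained period (default 120 s, emulating the lull after a train
departure) and builds one graph per segment; quiet frames attach to the
preceding segment so the segments exactly reconstitute the input. Windowing is
an efficiency measure only.

## RDF estimators and normalization

One container holds raw per-bin event counts plus the metadata needed to
renormalize exactly:

- *raw*: counts, with `G` their prefix sum;
- *total-N*: `g` scaled so `∫ g dr` equals the mean occupancy `N̄`;
- *density*: `G(r)` equal to the mean number of neighbors within `r` divided by
  the pair density, so `G(r) → π r²` for an unconfined uniform crowd.

Density normalization uses the ideal-gas pair density `ρ = (N̄ − 1)/A` — the
standard finite-N correction, without which a crowd of `N` uniform pedestrians
would read `G = π r² (N−1)/N`. `A` is the full rectangle area (the domain on
which placements and trajectories live), whereas the *usable area* (total
sensor area minus danger zone; with the 450 m² sensor-total convention,
450 − 96 = 354 m²) is used for occupancy-to-density conversion in the
stratified reporting, where the operational convention differs.

Exposure functionals: `T = ΔT · ρ · G(r_c)` with `G` interpolated linearly
between right bin edges (`G(0) = 0`), erroring outside the binned support;
`t(r) = ΔT · ρ · g(r)` at the bin containing `r`. A train-schedule correction
factor, when one applies, is a user-supplied multiplier on these outputs and is
deliberately not modeled.

## Monte Carlo baseline

The structureless reference crowd places `N` points uniformly in the rectangle
subject to a pairwise hard core of 0.2 m (a body-exclusion floor), by
sequential rejection with 10⁴ retries per point and up to 5 full restarts; a
loose hexagonal-packing bound rejects infeasible requests up front. At the
default platform densities the acceptance rate is near 1, so rejection sampling
is both exact (the conditional uniform law) and cheap.

Growth-exponent diagnostics fit log `G` against log `r` by least squares over
right bin edges in a window. The quadratic-regime window is **[0.5, 1.5] m**:
below ~0.5 m the hard core depletes the first bins (the local exponent there
exceeds 2.3), and above the platform half-width (1.5 m for a 3 m platform)
boundary clipping bends the curve toward the linear regime, whose window is
**[5, 30] m**. With 200 realizations of N = 75 on the 120 m × 3 m platform the
measured exponents are ≈ 1.97–2.04 and ≈ 0.95, i.e. the quadratic→linear
crossover sits at the platform width as confinement dictates. The
unconfined-limit check uses N = 1000 in a 200 × 200 m square (ρ = 0.025 ped/m²,
hard-core area fraction 0.08%) over r ∈ [2, 3] m, where the hard-core (≈1%)
and boundary (≈0.9%) deficits plus counting noise (per-bin SE ≈ 0.6% at 200
realizations) keep the deviation from `π r² ρ` near 2%.

## Classification

The family relation compares contact-time frame counts against persistence
frame counts directly, so the sampling frequency cancels; total (common +
danger) weights are used, since the relation is about social ties, not
location. Thresholds are strict (`>`), as are the offender thresholds. Both
endpoints must persist at least 10 s (configurable): very short or broken
tracks can trivially satisfy the proximity fractions and would inflate apparent
family-groups, and a minimal-persistence guard is the lightest mitigation.
Family-groups are maximal cliques of the relation (via networkx); the
transitive closure (connected components) is available but off by default —
chains `a∼b∼c` without `a∼c` are rare and closing them inflates groups on
noisy data.

Offender classification runs on the family-pruned graph `H′`:
`P′_α = {p : T_{p,f}^d > α}` with `d = 2` (r ≤ 1.5 m) as the regulation depth
and presets α ∈ {0, 10, 30} s (no single canonical α exists; exposure duration
is the operator's risk dial). The repeated-offender degree counts only
neighbors with at least one recorded event below `D = 1.5` m — proximity
between 1.5 and 2.5 m is recorded for statistics but is not an offense. Label
precedence: a clique member is always labeled `family-member`, even if it also
has non-family exposure above α (the report's label partition stays consistent
with its clique list); the unfiltered `P′_α` is reported separately so nothing
is hidden. Density-stratified reporting assigns each pedestrian the mean
ambient density over its observed frames and tabulates per-band fractions of
any-contact, family and offender nodes.

## Synthetic scenarios: what they emulate and what they do not

The generator emulates a platform crowd around train events: units (singles,
family-groups, wanderers) are assigned to boarding events, enter shortly after
the previous departure, walk to a hard-core-separated waiting spot, dwell, and
board through the danger zone. Families track a shared anchor with fixed
offsets on a circle of chord ≈ the intra-group distance (default mean 0.45 m,
comfortably inside the 1.0 m private-space bin), so their proximity fractions
exceed the family thresholds by construction margin; waiting strangers are
separated by ≥ 2 m (above regulation distance) so they never approach the
thresholds. Wanderers travel a low-`y` walking lane and dart up to pause ~2 s
at 0.7 m from each of ≥ 12 distinct waiting singles. Motion is
piecewise-linear at 1.0–1.5 m/s with i.i.d. Gaussian per-frame jitter of 0.05 m
per axis, matching the O(5–10 cm) localization noise of commercial overhead
sensors. Default entries are *aligned*: each unit enters the non-track edge
directly below its spot, so walk-in corridors are perpendicular and do not
sweep past other units — this is what makes "zero non-family exposure for
planted families" achievable at α = 0; with shared entry points (supported)
walk-ins realistically graze waiting strangers and small sporadic exposures
appear.

What the generator does **not** emulate: collision avoidance and social-force
interactions, broken/re-identified tracks, platform furniture, multi-sensor
stitching artifacts, or realistic arrival-process burstiness. Passing tests on
these scenarios therefore validates the *accounting* (conservation,
equivalence, threshold logic, recovery of structure planted with margins), not
the detector's error rates on real sensor data, where broken tracks and
borderline social configurations will produce genuine ambiguity.

## Problem sizes and numerical choices

Validation runs use a 200-pedestrian, ~2000-frame scenario spread over six
train events (the platform cannot physically hold 200 simultaneous pedestrians
at compliant separations), ten seeded 76-pedestrian scenarios for family
recovery, 200 Monte Carlo realizations for the confined ensemble and 200 of
N = 1000 for the unconfined limit — sizes at which the brute-force oracles
remain exact and the stochastic bands are comfortably resolved. All randomness
flows from explicit seeds (`numpy.random.default_rng`); scenario generation is
deterministic given its config. Degenerate inputs are handled explicitly:
empty trajectory sets produce empty graphs and flagged-empty RDF estimates,
zero-contact pairs make distance moments an error rather than a NaN, and
infeasible hard-core placements raise before looping forever.
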