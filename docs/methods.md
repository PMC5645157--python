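# Methods

This note records the models the package implements, the conventions and
numerical choices behind them, and what the synthetic study conditions do
and do not establish.

## The trade-off model

The reconstruction problem is: given the 3-D positions of N cortical
areas, the interareal Euclidean distance matrix D, and the in- and
out-degree of every area, find a directed graph minimizing

    L(A) = (1 − α) · l_g(A) / l_g^max + α · l_p(A) / l_p^max .

* `l_p` — total wiring length, the sum of `d_ij` over all *directed*
  links.  A reciprocal pair contributes its distance twice.  Since `l_p`
  only ever appears normalized by `l_p^max` (computed with the same
  convention), the choice cancels in L.
* `l_g = 1/e_g` — graph length, with `e_g` the mean of `1/l_ij` over
  ordered pairs i≠j of directed shortest-path lengths.  Unreachable pairs
  contribute 0 to `e_g` (the standard efficiency convention), which keeps
  the objective finite and automatically penalizes disconnection.
* Normalizers are calibrated by the two single-factor optimizations:
  `l_p^max` is the wiring cost of the pure-efficiency optimum (α = 0) and
  `l_g^max` the graph length of the pure-cost optimum (α = 1).

Assumptions worth keeping in mind: links are binary (no projection
weights), interareal distance is straight-line (fiber tracts are longer
but roughly proportional), and "function" enters only through the
efficiency term and the fixed degrees.

### Annealing protocol

Moves are directed double-edge swaps — (s1→t1, s2→t2) becomes (s1→t2,
s2→t1) — rejected when they would create a self-loop or duplicate link,
so both degree sequences are conserved exactly at every step.  Moves that
disconnect the network (directed reachability) are discarded without
counting toward acceptance statistics.  Each temperature level rewires
for `steps_per_level` (default 1000) counted proposals; a move with
ΔL < 0 is accepted, otherwise accepted with probability exp(−ΔL/T).

The temperature schedule is `T_{n+1} = T_n / n` with levels indexed from
1, i.e. two levels at T0 followed by a factorially fast quench; in
practice the run is a brief hot phase and a near-greedy descent.  The run
terminates once the best objective improves by ≤ `tol` (default 1e−5)
between consecutive levels, guarded by `max_levels` (default 10^4) and a
`min_levels` floor (default 12): during the hot phase the best objective
can stagnate for one level by chance, and by level ~12 the schedule has
cooled below T0/10^7, so the floor only prevents spurious early exits.

T0, when not supplied, is calibrated from a 200-swap probe of the initial
state so that the mean uphill move would be accepted with probability
~0.5.  A hotter start (e.g. calibrating to 80% uphill acceptance) was
found to overshoot the temperature window in which escaping local optima
still matters — the factorial quench passes through that window in only
one or two levels — and measurably degraded the fraction of exhaustively
enumerable 6-node instances on which the annealer reaches the global
optimum.  The 50% target fixes this and is the package default.

Wiring cost is updated in O(1) per swap; graph length is recomputed
exactly (no approximation) by a boolean matrix-product BFS, which at
N ≈ 100 is the fastest exact option in numpy.

### Consensus reconstruction

Each α is run from `realizations` (default 50; desk-scale runs use 8–15)
independent random degree-preserving initial states.  The link-frequency
matrix `P_ij` (fraction of realizations containing j→i) is thresholded to
the real link count K by ranking candidate links by frequency, breaking
ties at the threshold frequency by shorter Euclidean distance (favoring
the cost term that dominates the regime of interest; stable index order
when no distances are given).  Links never observed (P = 0) are not
added, so the achieved count is the closest attainable to K.  The
threshold `P_T` reported is the frequency of the last admitted link.

## Shared network measures

* Clustering, matching index and neighbor similarity operate on the
  symmetrized graph; betweenness and shortest paths stay directed.  This
  mirrors common connectome-toolbox behavior; a directed clustering
  variant is available behind a flag.
* Matching index `K(u,v)` excludes u and v themselves from the neighbor
  sets; the similarity `S_ij = M_ij/(K_i + K_j − M_ij)` used for
  dendrograms does not.  Both define 0/0 = 0.
* Betweenness is reported as raw shortest-path counts (not normalized).

## Generative model

Propensity `P(u,v) = d(u,v)^η · K(u,v)^γ`, defined up to a constant.
Twelve named topological rules are registered (spatial-only, common
neighbors, matching index, and pairwise min/max/avg/diff/product
combinations of degree or clustering); the matching-index rule is the one
exercised by the fitted analyses, and the others follow the standard
definitions used by generative-model toolboxes.

* Growth variant: a random seed network (default 464 directed edges among
  16 randomly chosen areas) is extended one link at a time, sampling
  ordered non-linked pairs proportionally to the propensity, with the
  topological term recomputed after every addition, until K links exist.
* Fixed-degree variant: starting from a degree-preserving randomization,
  double-edge swaps with no crossing connections are accepted with
  probability min(1, P(u1,v2)·P(u2,v1)/c).  The scale constant c is the
  maximum product observed in a 1000-swap probe of the initial state and
  is then *frozen*: updating c during the run makes acceptance collapse
  under heavy-tailed propensities (strongly negative η) and stalls the
  walk.  The run stops after `n_pairs` accepted swaps (default 200,000)
  or a hard cap of 20× that many proposals.
* Zero-valued topological terms are floored at 1e−6 × the median positive
  propensity so that γ > 0 cannot forbid all novel attachments.
* Fit quality is the KS energy: the maximum of the four two-sample
  Kolmogorov–Smirnov statistics over total degree, clustering,
  betweenness and edge length (fixed-degree models have KS_degree = 0 by
  construction).  Fitting scans an (η, γ) grid, scoring each point by the
  mean energy over `n_samples` model draws.

## Recovery, Z-scores and LDC identification

`r1` (`r0`) is the fraction of real links (off-diagonal non-links)
present (absent) in the model network.  Per-area recovery pools input and
output links.  Null benchmarks are ensembles of degree-preserving
randomizations (directed double-edge swaps, 10 attempted swaps per link;
connectivity of null members is not enforced); the per-area Z-score
compares the model's recovery with the coincident overlap of each null
member with the real links.

Long-distance connectors: the *core* set is areas with Z < −1.65 (the
one-sided 5% normal quantile) — areas the best trade-off model explains
significantly worse than chance.  The *extended* set is areas with
insignificant recovery (|Z| < 1.65) and intermediate-to-large total
degree.  The degree criterion is a configurable cut: 20 for the macaque
network (where it excludes the low-degree bottom fifth of areas whose
Z-scores are unstable), and the 20th percentile of total degree for
synthetic runs — the same operational rule expressed scale-free.  An
explicit candidate list can further restrict the extended set.  Set-level
tallies (e.g. the share of >30 mm links) count each directed link once if
either endpoint is in the set.

## Segregation and integration

* Dendrograms: agglomerative clustering on `1 − S_ij`.  The linkage
  method is configurable; single linkage is the default (average linkage
  available).  Cutting the tree at a threshold yields flat partitions;
  Newman modularity of each partition is evaluated on the symmetrized
  binary graph.
* Function-matched subtrees: the tree is cut at descending thresholds
  (step 0.01, from above the root to 0).  A cluster of not-yet-retained
  areas is frozen as a subtree when one functional system exceeds half of
  its members with more than 3 areas from that system; frozen subtrees
  are not divided further, and areas never captured form the non-cluster
  remainder.
* Diversity: `C_i = −Σ_J p_i(J) ln p_i(J)` over the five systems, with
  `p_i(J)` the fraction of area i's pooled links attached to system J;
  bounded by ln 5 ≈ 1.61, undefined (NaN) for isolated areas.
* Dense group: internal directed link density θ = links/(m(m−1)) of a
  node set, compared with the same set's density across the null
  ensemble (mean, SD, Z).  Computing θ for the top-degree nodes gives the
  conventional rich-club index.
* R-network: every real link touching an LDC that the consensus fails to
  reproduce is replaced by a random unconnected ordered pair from the
  same 5 mm distance bin (nearest non-empty bin as a logged fallback,
  required to stay below 5% of moved links).  Total links and the
  per-bin distance histogram — hence total wiring cost up to bin
  resolution — are conserved; degrees are not, by design, since the
  surrogate's purpose is to destroy the concentration of long links on
  particular areas at fixed cost.

## Synthetic study conditions

The generator emulates the features the analysis relies on: areas as
Gaussian clouds (σ = 6 mm) around five system centers spanning ~55 mm,
directed links drawn without replacement with probability ∝ exp(−d/λ)
(λ = 10 mm), and planted LDCs that receive a fixed number of links to
partners beyond 30 mm before the fill.  Defaults mirror the macaque
scale (N = 103, K = 2518, five systems, six connectors).  Two choices
deserve explanation:

* The short-range fill is damped (weight 0.15) on pairs touching a
  planted LDC.  Without this the fill gives connectors the same
  short-range degree as everyone else, their connectivity is no longer
  dominated by long links, and they cease to be long-distance connectors
  in the defining sense (their recovery under cost optimization is then
  *better* than chance).  The damping also keeps their total degree
  intermediate rather than hub-like.
* The weighted draw without replacement is implemented as Gumbel top-k on
  log-weights — exactly equivalent to sequential propensity-weighted
  draws, and immune to exponential underflow at small λ.  Sequential
  sampling induces mild deviations from an independent-Bernoulli model;
  none of the analyses assume independence.

What the synthetic conditions do **not** emulate: projection weights,
reciprocity statistics of real tract-tracing data, cortical surface
geometry (distances are straight-line between Gaussian-cloud points), and
heterogeneous system sizes.  Passing the planted-recovery tests therefore
shows that the pipeline detects the targeted signature (excess
long-range connectivity at fixed degrees) at realistic size and density,
not that it would detect every biological connector.

## Problem sizes

Tests and the acceptance script keep runs desk-scale as a deliberate
choice of study conditions: trade-off sweeps on a 60-area, 850-link
network with 8 realizations per α; planted-LDC recovery on 40-area,
320-link networks (4 connectors, 12 long links each) with 10 realizations
and null ensembles of 50; generative fits on a 3×3 (η, γ) grid with
20,000 accepted swaps and 2 draws per point.  The exhaustive annealing
oracle enumerates all 1722 degree-matched digraphs of a 6-node, 10-link
instance.  Full-protocol settings (50 realizations, 200,000 swaps,
13×13 grids, 100-member nulls) remain the library defaults.

## Known limitations

* Binary connectivity only; no weighted variants of the metrics or
  models.
* The annealing schedule quenches factorially, so results at α strictly
  between 0 and 1 depend mostly on the calibrated T0 and the greedy
  phase; consensus over restarts, not individual runs, is the intended
  estimator.
* Single-linkage dendrograms can chain; the linkage method is exposed
  precisely because printed subtree thresholds are the only calibration
  anchor available for real data.
* The extended-LDC rule involves a degree criterion that is inherently a
  convention; it is exposed as a parameter rather than hidden.
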