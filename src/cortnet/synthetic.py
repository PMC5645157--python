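"""Synthetic spatially embedded connectomes with planted structure.

The generator emulates the statistical structure the analysis pipeline
assumes of primate cortico-cortical data: areas laid out as Gaussian
clouds around five spatially separated "functional system" centers,
directed connectivity whose probability decays exponentially with
Euclidean distance, and a small set of planted long-distance-connector
(LDC) nodes that carry an excess of links longer than a cutoff (30 mm by
default).  Defaults mirror the scale of the macaque cortical dataset the
pipeline targets (103 areas, 2518 directed links, five systems); every
pipeline stage can therefore be exercised without any downloaded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from cortnet.data import SYSTEMS, SpatialNetwork

#: Default functional-system centers (mm): five clusters spanning ~55 mm,
#: comparable to the extent of a macaque hemisphere, with several
#: inter-center separations above the 30 mm long-link cutoff.
DEFAULT_CENTERS = np.array([
    [0.0, 0.0, 0.0],
    [26.0, 8.0, 4.0],
    [10.0, 28.0, 6.0],
    [40.0, 24.0, 0.0],
    [52.0, 6.0, 8.0],
])


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic connectome generator."""

    N: int = 103
    K: int = 2518
    n_systems: int = 5
    system_centers: np.ndarray | None = None
    spatial_scale: float = 6.0       # per-cluster Gaussian sigma, mm
    decay_length: float = 10.0       # lambda of exp(-d / lambda), mm
    n_ldc: int = 6
    ldc_long_links_per_node: int = 20
    ldc_short_weight: float = 0.15   # damping of the short-range fill at LDCs
    long_cut: float = 30.0           # mm
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.K > self.N * (self.N - 1):
            raise ValueError("K exceeds the number of ordered pairs")
        if self.n_ldc >= self.N:
            raise ValueError("n_ldc must be smaller than N")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")


@dataclass
class SyntheticTruth:
    """Planted parameters of a generated network."""

    system: np.ndarray            # per-node system label
    ldc_ids: np.ndarray           # planted LDC node indices
    edge_distances: np.ndarray    # realized directed link lengths, mm
    spec: SyntheticSpec


def generate(
    spec: SyntheticSpec,
    rng: np.random.Generator | None = None,
) -> tuple[SpatialNetwork, SyntheticTruth]:
    """Sample a network from the spec; same seed gives identical output.

    Long LDC links are placed first so the total link count lands on K
    exactly; the remaining links are drawn without replacement with
    probability proportional to exp(-d / decay_length).
    """
    rng = np.random.default_rng(spec.seed if rng is None else rng)
    centers = (np.asarray(spec.system_centers, dtype=float)
               if spec.system_centers is not None
               else DEFAULT_CENTERS[: spec.n_systems])
    if len(centers) != spec.n_systems:
        raise ValueError("need one center per system")

    # node layout: balanced assignment to Gaussian clouds
    sizes = np.full(spec.n_systems, spec.N // spec.n_systems)
    sizes[: spec.N % spec.n_systems] += 1
    system = np.concatenate([
        np.full(s, SYSTEMS[i % len(SYSTEMS)], dtype=object)
        for i, s in enumerate(sizes)
    ])
    coords = np.concatenate([
        centers[i] + rng.normal(0.0, spec.spatial_scale, size=(s, 3))
        for i, s in enumerate(sizes)
    ])
    D = cdist(coords, coords)
    n = spec.N
    A = np.zeros((n, n), dtype=np.int8)
    off = ~np.eye(n, dtype=bool)

    # planted LDCs, spread across systems; only nodes with enough
    # partners beyond the long cutoff are eligible hosts
    ldc_ids = np.array([], dtype=int)
    if spec.n_ldc > 0:
        n_far = (D > spec.long_cut).sum(axis=1)
        feasible = 2 * n_far >= spec.ldc_long_links_per_node
        per_sys = np.array_split(np.arange(spec.n_ldc), spec.n_systems)
        chosen: list[int] = []
        start = np.concatenate([[0], np.cumsum(sizes)])
        short = 0
        for i, chunk in enumerate(per_sys):
            if len(chunk) == 0:
                continue
            pool = np.arange(start[i], start[i + 1])
            pool = pool[feasible[pool]]
            take = min(len(chunk) + short, len(pool))
            short = len(chunk) + short - take
            if take:
                chosen.extend(rng.choice(pool, size=take, replace=False))
        if short:
            raise ValueError(
                f"only {len(chosen)} of {spec.n_ldc} LDCs can host "
                f"{spec.ldc_long_links_per_node} links beyond "
                f"{spec.long_cut} mm")
        ldc_ids = np.sort(np.asarray(chosen, dtype=int))

    # excess long-range links of the planted LDCs, placed first
    for node in ldc_ids:
        eligible = np.flatnonzero((D[node] > spec.long_cut))
        want = spec.ldc_long_links_per_node
        placed = 0
        partners = rng.permutation(np.repeat(eligible, 2))
        for p in partners:
            if placed >= want:
                break
            if rng.random() < 0.5:
                s, t = node, p
            else:
                s, t = p, node
            for s, t in ((s, t), (t, s)):
                if not A[t, s]:
                    A[t, s] = 1
                    placed += 1
                    break
        if placed < want:
            raise ValueError(
                f"node {node}: only {placed} of {want} long links placeable")

    # distance-decay fill to K links (sequential weighted draws w/o repl.)
    remaining = spec.K - int(A.sum())
    if remaining < 0:
        raise ValueError("planted long links exceed the link budget K")
    free = off & (A == 0)
    ft, fs = np.nonzero(free)
    logw = -D[ft, fs] / spec.decay_length
    if len(ldc_ids):
        # LDC connectivity must stay dominated by its long links, so the
        # ordinary short-range fill is damped on pairs touching an LDC
        is_ldc = np.zeros(n, dtype=bool)
        is_ldc[ldc_ids] = True
        logw = logw + np.where(is_ldc[ft] | is_ldc[fs],
                               np.log(spec.ldc_short_weight), 0.0)
    # Gumbel top-k == sequential weighted draws without replacement,
    # and is immune to exp underflow at small decay lengths
    gumbel = -np.log(-np.log(rng.random(len(ft))))
    pick = np.argsort(-(logw + gumbel))[:remaining]
    A[ft[pick], fs[pick]] = 1

    names = [f"{system[i]}{i:03d}" for i in range(n)]
    net = SpatialNetwork(area_ids=names, coords=coords, A=A, system=system)
    truth = SyntheticTruth(
        system=system.copy(),
        ldc_ids=ldc_ids,
        edge_distances=D[A.astype(bool)],
        spec=spec,
    )
    return net, truth


# ---------------------------------------------------------------------------
# deterministic toy fixtures shared across test suites
# ---------------------------------------------------------------------------


def fixture_library() -> dict[str, SpatialNetwork]:
    """Named deterministic toy instances.

    * ``three_cycle``: directed 3-cycle (graph length 4/3);
    * ``two_cliques``: two 4-cliques with no shared neighbors, joined by a
      single reciprocal bridge (dendrogram separates the cliques first);
    * ``anneal_toy6``: strongly connected 6-node, 10-link instance with
      irregular coordinates, small enough for exhaustive enumeration of
      all degree-preserving digraphs;
    * ``planted_ldc40``: 40-node synthetic network with 4 planted LDCs.
    """
    lib: dict[str, SpatialNetwork] = {}

    A3 = np.zeros((3, 3), dtype=int)
    for s, t in [(0, 1), (1, 2), (2, 0)]:
        A3[t, s] = 1
    lib["three_cycle"] = SpatialNetwork(
        area_ids=["a", "b", "c"],
        coords=np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float),
        A=A3,
    )

    n = 8
    Ac = np.zeros((n, n), dtype=int)
    for grp in (range(4), range(4, 8)):
        for u in grp:
            for v in grp:
                if u != v:
                    Ac[v, u] = 1
    Ac[4, 0] = Ac[0, 4] = 1  # reciprocal bridge
    coords = np.array(
        [[i % 2, i // 2, 0] for i in range(4)]
        + [[10 + i % 2, i // 2, 0] for i in range(4)], dtype=float)
    lib["two_cliques"] = SpatialNetwork(
        area_ids=[f"c{i}" for i in range(n)], coords=coords, A=Ac)

    A6 = np.zeros((6, 6), dtype=int)
    for s, t in [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5), (5, 0),
                 (0, 3), (3, 0), (1, 4), (2, 5)]:
        A6[t, s] = 1
    coords6 = np.array([
        [0.0, 0.0, 0.0], [3.0, 1.0, 0.0], [6.0, 0.0, 1.0],
        [7.0, 4.0, 0.0], [2.0, 5.0, 1.0], [0.0, 3.0, 2.0],
    ])
    lib["anneal_toy6"] = SpatialNetwork(
        area_ids=[f"t{i}" for i in range(6)], coords=coords6, A=A6)

    spec = SyntheticSpec(N=40, K=320, n_ldc=4, ldc_long_links_per_node=12,
                         spatial_scale=4.0, decay_length=8.0, seed=2024)
    net, truth = generate(spec)
    net.truth = truth  # attach planted truth for tests
    lib["planted_ldc40"] = net
    return lib
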