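"""Distance x topology generative model and its fixed-degree extension.

A link between areas u and v is laid down with propensity

    P(u, v) = E(u, v)**eta * K(u, v)**gamma

where E is the Euclidean distance and K a topological affinity term (the
matching index by default).  Two variants are implemented:

* growth: starting from a small random seed network, directed edges are
  added one at a time, sampled proportionally to P(u, v) with K recomputed
  as the topology evolves, until the target link count is reached;
* fixed degrees: starting from a degree-preserving randomization of the
  real network, double-edge swaps are accepted with probability
  proportional to P(u1, v2) * P(u2, v1), so degrees are conserved exactly.

Model fit is scored by the KS energy: the maximum of four two-sample
Kolmogorov-Smirnov distances (degree, clustering, betweenness, edge
length) between the model and the real network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import ks_2samp

from cortnet._graph import symmetrize
from cortnet.data import SpatialNetwork, randomize_preserving_degrees
from cortnet.metrics import (
    betweenness_centrality,
    clustering_coefficients,
    edge_lengths,
    matching_index,
)

# ---------------------------------------------------------------------------
# topological-rule registry
# ---------------------------------------------------------------------------


def _rule_spatial(A):
    n = A.shape[0]
    return np.ones((n, n))


def _rule_neighbors(A):
    B = symmetrize(A).astype(np.int64)
    return (B @ B).astype(float)


def _rule_matching(A):
    return matching_index(A)


def _deg_rule(fn):
    def rule(A):
        B = symmetrize(A).astype(np.int64)
        k = B.sum(axis=1).astype(float)
        return fn(k[:, None], k[None, :])
    return rule


def _clu_rule(fn):
    def rule(A):
        c = clustering_coefficients(A)
        return fn(c[:, None], c[None, :])
    return rule


#: The 12 named topological rules. Only ``matching`` is exercised in the
#: fitted analyses; the remaining rules follow the standard definitions
#: (pairwise combinations of degree or clustering, common-neighbor count,
#: purely spatial).
RULES = {
    "sptl": _rule_spatial,
    "neighbors": _rule_neighbors,
    "matching": _rule_matching,
    "deg-avg": _deg_rule(lambda a, b: (a + b) / 2.0),
    "deg-min": _deg_rule(np.minimum),
    "deg-max": _deg_rule(np.maximum),
    "deg-diff": _deg_rule(lambda a, b: np.abs(a - b)),
    "deg-prod": _deg_rule(lambda a, b: a * b),
    "clu-avg": _clu_rule(lambda a, b: (a + b) / 2.0),
    "clu-min": _clu_rule(np.minimum),
    "clu-max": _clu_rule(np.maximum),
    "clu-diff": _clu_rule(lambda a, b: np.abs(a - b)),
}


@dataclass
class GenerativeParams:
    """Parameters of the generative rules.

    ``eta`` is the distance exponent (negative values favour short links),
    ``gamma`` the topology exponent. ``seed_nodes``/``seed_edges`` describe
    the random seed network of the growth variant; ``n_pairs`` is the
    number of accepted swaps in the fixed-degree variant.
    """

    eta: float = -1.0
    gamma: float = 1.0
    rule: str = "matching"
    n_pairs: int = 200_000
    seed_nodes: int = 16
    seed_edges: int = 464
    k_floor_frac: float = 1e-6   # zero-K floor, as a fraction of the median

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(
                f"unknown rule {self.rule!r}; choose from {sorted(RULES)}")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")


@dataclass
class EnergyReport:
    ks_degree: float
    ks_clustering: float
    ks_betweenness: float
    ks_edge_length: float

    @property
    def energy(self) -> float:
        return max(self.ks_degree, self.ks_clustering,
                   self.ks_betweenness, self.ks_edge_length)


def _floor_topo(K: np.ndarray, gamma: float, frac: float) -> np.ndarray:
    """Floor zero affinities so gamma > 0 cannot forbid novel attachments."""
    if gamma == 0:
        return np.ones_like(K)
    pos = K[K > 0]
    eps = frac * (np.median(pos) if pos.size else 1.0)
    return np.maximum(K, eps)


def link_probability(
    D: np.ndarray,
    K_topo: np.ndarray,
    params: GenerativeParams,
) -> np.ndarray:
    """Unnormalized propensity E**eta * K**gamma for every ordered pair.

    The diagonal is zeroed; zero-valued topological terms are floored at a
    small fraction of the median positive propensity.
    """
    D = np.asarray(D, dtype=float)
    off = ~np.eye(D.shape[0], dtype=bool)
    if (D[off] <= 0).any():
        raise ValueError("off-diagonal distances must be positive")
    Kf = _floor_topo(np.asarray(K_topo, dtype=float), params.gamma,
                     params.k_floor_frac)
    with np.errstate(divide="ignore"):
        P = D ** params.eta * Kf ** params.gamma
    P[~off] = 0.0
    return P


def grow_network(
    D: np.ndarray,
    K_target: int,
    params: GenerativeParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Growth variant: random seed, then one sampled edge per step.

    Adds directed edges proportionally to the current propensity matrix,
    recomputing the topological term after every addition, until exactly
    ``K_target`` links exist.
    """
    rng = np.random.default_rng(rng)
    n = D.shape[0]
    A = np.zeros((n, n), dtype=np.int8)
    rule = RULES[params.rule]
    # random seed network among randomly selected regions
    seed_nodes = rng.choice(n, size=min(params.seed_nodes, n), replace=False)
    m = len(seed_nodes)
    pairs = [(u, v) for u in seed_nodes for v in seed_nodes if u != v]
    n_seed = min(params.seed_edges, len(pairs), K_target)
    for idx in rng.choice(len(pairs), size=n_seed, replace=False):
        u, v = pairs[idx]
        A[v, u] = 1
    off = ~np.eye(n, dtype=bool)
    while A.sum() < K_target:
        P = link_probability(D, rule(A), params)
        P[A > 0] = 0.0
        total = P.sum()
        if total <= 0:
            raise RuntimeError("no addable pair remains")
        flat = P.ravel() / total
        choice = rng.choice(n * n, p=flat)
        A.ravel()[choice] = 1
    return A


def rewire_fixed_degrees(
    net: SpatialNetwork | np.ndarray,
    D: np.ndarray,
    params: GenerativeParams,
    rng: np.random.Generator | None = None,
    randomize_start: bool = True,
) -> np.ndarray:
    """Fixed-degree variant: propensity-guided double-edge swaps.

    Starting from a degree-preserving randomization of the input network,
    two links (u1->v1), (u2->v2) with no crossing connections are exchanged
    with probability min(1, P(u1,v2) * P(u2,v1) / c), where c is the
    running-maximum product observed in a 1000-swap probe (the propensities
    of the generative rules are defined only up to a constant).  Runs until
    ``params.n_pairs`` swaps are accepted or a hard proposal cap of
    20 x n_pairs is reached.
    """
    rng = np.random.default_rng(rng)
    A0 = (net.A if isinstance(net, SpatialNetwork) else np.asarray(net))
    A = (randomize_preserving_degrees(A0, 10, rng) if randomize_start
         else A0.copy().astype(np.int8))
    tgt, src = np.nonzero(A)
    edges = np.column_stack([src, tgt])
    k = len(edges)
    if k < 2:
        return A
    B = symmetrize(A).astype(np.int8)
    eta, gamma = params.eta, params.gamma
    use_matching = params.rule == "matching"
    rule = RULES[params.rule]

    if use_matching:
        Km0 = matching_index(A)
        pos = Km0[Km0 > 0]
    else:
        K_full = rule(A)
        pos = K_full[K_full > 0]
    k_eps = params.k_floor_frac * (float(np.median(pos)) if pos.size else 1.0)

    def pair_topo(u, v):
        """Topological term of the ordered pair under the current state."""
        if use_matching:
            common = int(np.dot(B[u], B[v]))
            union = int(B[u].sum() + B[v].sum() - B[u, v] - B[v, u] - common)
            kval = common / union if union > 0 else 0.0
        else:
            kval = float(rule(A)[u, v])
        return max(kval, k_eps) if gamma != 0 else 1.0

    def product(u1, v2, u2, v1):
        return ((D[u1, v2] ** eta) * (pair_topo(u1, v2) ** gamma)
                * (D[u2, v1] ** eta) * (pair_topo(u2, v1) ** gamma))

    def set_edge(s, t, val):
        A[t, s] = val
        if val:
            B[s, t] = B[t, s] = 1
        elif not A[s, t]:
            B[s, t] = B[t, s] = 0

    # scale-calibration probe: running maximum product over 1000 proposals
    c = 0.0
    probed = 0
    while probed < 1000:
        e1, e2 = rng.integers(0, k, size=2)
        if e1 == e2:
            continue
        s1, t1 = edges[e1]
        s2, t2 = edges[e2]
        probed += 1
        if s1 == t2 or s2 == t1 or A[t2, s1] or A[t1, s2]:
            continue
        c = max(c, product(s1, t2, s2, t1))
    if c <= 0:
        c = 1.0

    accepted = 0
    proposals = 0
    cap = 20 * params.n_pairs
    while accepted < params.n_pairs and proposals < cap:
        proposals += 1
        e1, e2 = rng.integers(0, k, size=2)
        if e1 == e2:
            continue
        s1, t1 = edges[e1]
        s2, t2 = edges[e2]
        if s1 == t2 or s2 == t1 or s1 == s2 or t1 == t2:
            continue
        if A[t2, s1] or A[t1, s2]:
            continue
        prod = product(s1, t2, s2, t1)
        if rng.random() < min(1.0, prod / c):
            set_edge(s1, t1, 0)
            set_edge(s2, t2, 0)
            set_edge(s1, t2, 1)
            set_edge(s2, t1, 1)
            edges[e1] = (s1, t2)
            edges[e2] = (s2, t1)
            accepted += 1
    return A


def ks_energy(
    A_model: np.ndarray,
    A_real: np.ndarray,
    D: np.ndarray,
) -> EnergyReport:
    """KS distances between model and real feature distributions.

    Features: total degree (in+out), clustering coefficient (symmetrized),
    betweenness centrality (directed), edge length. Energy is their max.
    """
    A_model = np.asarray(A_model)
    A_real = np.asarray(A_real)
    if A_model.shape != A_real.shape:
        raise ValueError("model and real networks must have the same size")
    if A_model.sum() == 0 or A_real.sum() == 0:
        raise ValueError("KS energy undefined for an empty edge set")

    def ks(x, y):
        return float(ks_2samp(x, y).statistic)

    deg_m = A_model.sum(0) + A_model.sum(1)
    deg_r = A_real.sum(0) + A_real.sum(1)
    return EnergyReport(
        ks_degree=ks(deg_m, deg_r),
        ks_clustering=ks(clustering_coefficients(A_model),
                         clustering_coefficients(A_real)),
        ks_betweenness=ks(betweenness_centrality(A_model),
                          betweenness_centrality(A_real)),
        ks_edge_length=ks(edge_lengths(A_model, D), edge_lengths(A_real, D)),
    )


def fit_parameters(
    net: SpatialNetwork,
    D: np.ndarray,
    grid: list[tuple[float, float]],
    n_samples: int = 10,
    rng: np.random.Generator | None = None,
    rule: str = "matching",
    fixed_degrees: bool = True,
    n_pairs: int | None = None,
) -> dict:
    """Grid search over (eta, gamma) minimizing the mean KS energy.

    Each grid point is scored by the mean energy over ``n_samples``
    independent model draws; the argmin together with the full energy
    surface is returned.
    """
    if not grid:
        raise ValueError("parameter grid is empty")
    rng = np.random.default_rng(rng)
    surface = []
    best = None
    for eta, gamma in grid:
        params = GenerativeParams(eta=eta, gamma=gamma, rule=rule)
        if n_pairs is not None:
            params.n_pairs = n_pairs
        energies = []
        reports = []
        for _ in range(n_samples):
            if fixed_degrees:
                A_m = rewire_fixed_degrees(net, D, params, rng)
            else:
                A_m = grow_network(D, net.n_links, params, rng)
            rep = ks_energy(A_m, net.A, D)
            energies.append(rep.energy)
            reports.append(rep)
        mean_e = float(np.mean(energies))
        surface.append((eta, gamma, mean_e))
        if best is None or mean_e < best["energy"]:
            best = {
                "eta": eta, "gamma": gamma, "energy": mean_e,
                "report": reports[int(np.argmin(energies))],
            }
    return {"best": best, "surface": surface}


def default_grid(
    eta_range=(-6.0, 0.0),
    gamma_range=(0.0, 6.0),
    n: int = 13,
) -> list[tuple[float, float]]:
    """Default (eta, gamma) search grid."""
    etas = np.linspace(*eta_range, n)
    gammas = np.linspace(*gamma_range, n)
    return [(float(e), float(g)) for e in etas for g in gammas]
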